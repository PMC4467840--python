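"""Conservation scoring of NOLP intervals by a branch-length scale
likelihood-ratio test.

The neutral model is a rooted tree with branch lengths in expected
substitutions/site plus a general reversible (GTR) rate matrix and its
equilibrium base frequencies. For each locus a single scale parameter rho
multiplies every branch length; the likelihood is maximised over rho and
compared to the neutral likelihood at rho = 1:

    D = 2 (lnL_alt - lnL_null),   p = upper tail of chi-squared, df = 1.

rho < 1 means the locus accumulates fewer substitutions than neutral DNA
(conservation), rho > 1 means acceleration. A locus is called conserved when
p < alpha and rho < 1. Gaps, Ns and species missing from the alignment are
marginalised (treated as missing data, not a fifth state).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

from .io import FormatError

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}
MISSING = 4

SCALE_BOUNDS = (1e-3, 10.0)
SCALE_TOL = 1e-6
MIN_USABLE_COLUMNS = 10


# ---------------------------------------------------------------------------
# Tree


@dataclass
class TreeNode:
    name: str | None
    length: float  # branch to parent; 0.0 for the root
    children: list["TreeNode"] = field(default_factory=list)

    def postorder(self):
        for child in self.children:
            yield from child.postorder()
        yield self

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.postorder() if not n.children]


def parse_newick(text: str) -> TreeNode:
    tree = dendropy.Tree.get(data=text, schema="newick")

    def convert(dnode) -> TreeNode:
        name = dnode.taxon.label if dnode.taxon else dnode.label
        node = TreeNode(name=name, length=dnode.edge.length or 0.0)
        node.children = [convert(c) for c in dnode.child_nodes()]
        return node

    return convert(tree.seed_node)


def tree_to_newick(node: TreeNode) -> str:
    def fmt(n: TreeNode) -> str:
        if not n.children:
            return f"{n.name}:{n.length:.6g}"
        inner = ",".join(fmt(c) for c in n.children)
        label = n.name or ""
        return f"({inner}){label}:{n.length:.6g}"

    inner = ",".join(fmt(c) for c in node.children)
    return f"({inner});"


# ---------------------------------------------------------------------------
# Model


class NeutralModel:
    """Tree + reversible rate matrix + equilibrium frequencies.

    The rate matrix is normalised on construction so the mean substitution
    rate at equilibrium is 1 per unit branch length.
    """

    def __init__(self, tree: TreeNode, rate_matrix: np.ndarray, base_freqs: np.ndarray):
        pi = np.asarray(base_freqs, dtype=float)
        Q = np.asarray(rate_matrix, dtype=float)
        if pi.shape != (4,) or not np.isclose(pi.sum(), 1.0, atol=1e-6):
            raise ValueError("base_freqs must be 4 values summing to 1")
        if Q.shape != (4, 4):
            raise ValueError("rate_matrix must be 4x4")
        if not np.allclose(Q.sum(axis=1), 0.0, atol=1e-3):
            raise ValueError("rate matrix rows must sum to 0")
        # absorb round-off (e.g. from fixed-precision model files) into the diagonal
        Q = Q.copy()
        np.fill_diagonal(Q, np.diag(Q) - Q.sum(axis=1))
        flux = pi[:, None] * Q
        if not np.allclose(flux, flux.T, rtol=1e-4, atol=1e-8):
            raise ValueError("rate matrix violates detailed balance for base_freqs")
        mean_rate = -np.sum(pi * np.diag(Q))
        self.pi = pi / pi.sum()
        self.Q = Q / mean_rate
        self.tree = tree
        self.leaf_names = [n.name for n in tree.leaves()]
        # reversible Q diagonalises via the pi-symmetrised form
        d = np.sqrt(self.pi)
        S = (self.Q * d[:, None]) / d[None, :]
        w, U = np.linalg.eigh((S + S.T) / 2.0)
        self._w = w
        self._left = U / d[:, None]       # diag(1/sqrt(pi)) U
        self._right = (U * d[:, None]).T  # U^T diag(sqrt(pi))
        # flat edge arrays for fast pruning
        self._post = [n for n in tree.postorder()]
        self._index = {id(n): i for i, n in enumerate(self._post)}

    @classmethod
    def gtr(
        cls,
        tree: TreeNode,
        base_freqs,
        exchangeabilities=(1.0, 1.0, 1.0, 1.0, 1.0, 1.0),
    ) -> "NeutralModel":
        """Build a GTR matrix from exchangeabilities (AC, AG, AT, CG, CT, GT)
        and equilibrium frequencies."""
        pi = np.asarray(base_freqs, dtype=float)
        s = np.zeros((4, 4))
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        for (i, j), x in zip(pairs, exchangeabilities):
            s[i, j] = s[j, i] = x
        Q = s * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return cls(tree, Q, pi)

    @classmethod
    def hky(cls, tree: TreeNode, base_freqs, kappa: float = 2.0) -> "NeutralModel":
        """HKY85 as the GTR special case with transition/transversion ratio
        ``kappa`` (transitions AG and CT weighted kappa)."""
        return cls.gtr(tree, base_freqs, (1.0, kappa, 1.0, 1.0, kappa, 1.0))

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt), via the cached eigendecomposition."""
        P = (self._left * np.exp(self._w * t)[None, :]) @ self._right
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def branch_matrices(self, scale: float) -> list[np.ndarray | None]:
        """Transition matrices per postorder node (None for the root)."""
        out: list[np.ndarray | None] = []
        root = self._post[-1]
        for node in self._post:
            out.append(None if node is root else self.transition_matrix(node.length * scale))
        return out


def encode_columns(columns: list[str]) -> np.ndarray:
    """Encode alignment columns (one string per column, one char per species)
    into a (ncols, nspecies) int8 matrix; anything outside ACGT is missing."""
    if not columns:
        return np.zeros((0, 0), dtype=np.int8)
    arr = np.full((len(columns), len(columns[0])), MISSING, dtype=np.int8)
    for i, col in enumerate(columns):
        for j, c in enumerate(col):
            arr[i, j] = _CODE.get(c, MISSING)
    return arr


class LocusLikelihood:
    """Felsenstein pruning for one locus, vectorised over (pattern-compressed)
    alignment columns.

    ``codes`` is (ncols, nspecies) with species in ``species`` order; species
    are matched to tree leaves by name, tree leaves absent from ``species``
    are treated as all-missing.
    """

    def __init__(self, model: NeutralModel, codes: np.ndarray, species: list[str]):
        self.model = model
        nleaves = len(model.leaf_names)
        ncols = codes.shape[0]
        col_of = {sp: j for j, sp in enumerate(species)}
        leaf_codes = np.full((ncols, nleaves), MISSING, dtype=np.int8)
        for i, name in enumerate(model.leaf_names):
            j = col_of.get(name)
            if j is not None:
                leaf_codes[:, i] = codes[:, j]
        usable = (leaf_codes != MISSING).sum(axis=1) >= 2
        leaf_codes = leaf_codes[usable]
        self.n_usable = int(usable.sum())
        # pattern compression
        if self.n_usable:
            patterns, counts = np.unique(leaf_codes, axis=0, return_counts=True)
        else:
            patterns = leaf_codes
            counts = np.zeros(0)
        self.counts = counts.astype(float)
        # leaf partials: one-hot, missing -> ones
        eye5 = np.vstack([np.eye(4), np.ones(4)])
        self._leaf_partials = {}
        for i, name in enumerate(model.leaf_names):
            self._leaf_partials[name] = eye5[patterns[:, i]] if len(patterns) else np.ones((0, 4))

    @property
    def testable(self) -> bool:
        return self.n_usable >= MIN_USABLE_COLUMNS

    def log_likelihood(self, scale: float) -> float:
        """Summed column log-likelihood at the given branch-length scale."""
        if scale <= 0:
            raise ValueError("scale must be positive")
        model = self.model
        if len(self.counts) == 0:
            return 0.0
        mats = model.branch_matrices(scale)
        partial: dict[int, np.ndarray] = {}
        for idx, node in enumerate(model._post):
            if not node.children:
                partial[idx] = self._leaf_partials[node.name]
            else:
                prod = None
                for child in node.children:
                    ci = model._index[id(child)]
                    msg = partial.pop(ci) @ mats[ci].T
                    prod = msg if prod is None else prod * msg
                partial[idx] = prod
        root_lik = partial[len(model._post) - 1] @ model.pi
        logs = np.where(root_lik > 0, np.log(np.maximum(root_lik, 1e-300)), -np.inf)
        return float(np.dot(self.counts, logs))


def column_log_likelihood(
    column: str, model: NeutralModel, scale: float, species: list[str] | None = None
) -> float:
    """Log-likelihood of one alignment column (chars in tree-leaf order unless
    ``species`` is given); gaps/N marginalised."""
    species = species or model.leaf_names
    codes = encode_columns([column])
    loc = LocusLikelihood.__new__(LocusLikelihood)
    loc.model = model
    eye5 = np.vstack([np.eye(4), np.ones(4)])
    col_of = {sp: j for j, sp in enumerate(species)}
    loc._leaf_partials = {}
    for name in model.leaf_names:
        j = col_of.get(name)
        code = codes[0, j] if j is not None else MISSING
        loc._leaf_partials[name] = eye5[np.array([code])]
    loc.counts = np.ones(1)
    loc.n_usable = 1
    return loc.log_likelihood(scale)


@dataclass
class ScaleLRTResult:
    scale: float
    lnL_null: float
    lnL_alt: float
    D: float
    p_value: float
    direction: str  # conserved | accelerated | neutral
    testable: bool = True
    p_adjusted: float | None = None


def fit_scale(
    columns: list[str] | np.ndarray,
    model: NeutralModel,
    species: list[str] | None = None,
) -> tuple[float, float, LocusLikelihood]:
    """MLE of the branch-length scale for one locus by bounded 1-D search.

    Returns ``(scale_hat, lnL_alt, locus)``; the caller checks
    ``locus.testable``.
    """
    species = species or model.leaf_names
    codes = columns if isinstance(columns, np.ndarray) else encode_columns(list(columns))
    locus = LocusLikelihood(model, codes, species)
    if not locus.testable:
        return 1.0, locus.log_likelihood(1.0), locus
    res = minimize_scalar(
        lambda s: -locus.log_likelihood(s),
        bounds=SCALE_BOUNDS,
        method="bounded",
        options={"xatol": SCALE_TOL},
    )
    return float(res.x), float(-res.fun), locus


def scale_lrt(
    columns: list[str] | np.ndarray,
    model: NeutralModel,
    species: list[str] | None = None,
) -> ScaleLRTResult:
    """Scale LRT for one locus: D = 2(lnL_alt - lnL_null), chi-squared df=1."""
    scale, lnL_alt, locus = fit_scale(columns, model, species)
    lnL_null = locus.log_likelihood(1.0)
    if not locus.testable:
        return ScaleLRTResult(1.0, lnL_null, lnL_null, 0.0, 1.0, "neutral", testable=False)
    if lnL_alt < lnL_null:  # optimiser did not beat the null: clamp to neutral
        scale, lnL_alt = 1.0, lnL_null
    D = 2.0 * (lnL_alt - lnL_null)
    p = float(chi2.sf(D, df=1))
    if D == 0.0 or scale == 1.0:
        direction = "neutral"
    else:
        direction = "conserved" if scale < 1.0 else "accelerated"
    return ScaleLRTResult(scale, lnL_null, lnL_alt, D, p, direction)


def holm_bonferroni(p_values, alpha: float = 0.05):
    """Step-down Holm-Bonferroni adjustment.

    Returns ``(adjusted, reject)`` in the original order; ``adjusted[i]`` is
    the running maximum of ``(m - j + 1) * p_(j)`` over the sorted prefix,
    capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    mults = (m - np.arange(m)) * p[order]
    adj_sorted = np.minimum(np.maximum.accumulate(mults), 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    return adjusted, adjusted < alpha


def call_conserved(
    results: list[ScaleLRTResult], alpha: float = 0.05, use_adjusted: bool = False
) -> tuple[bool, int]:
    """Conservation call over the per-NOLP-interval LRT results.

    Conserved iff any testable interval has p < alpha and scale < 1; also
    returns how many intervals individually pass (NATs can carry two or more
    significantly conserved regions).
    """
    n_sig = 0
    for r in results:
        if not r.testable:
            continue
        p = r.p_adjusted if use_adjusted else r.p_value
        if p is None:
            p = r.p_value
        if p < alpha and r.scale < 1.0:
            n_sig += 1
    return n_sig > 0, n_sig


# ---------------------------------------------------------------------------
# phyloFit-style model text


def read_neutral_model(path) -> NeutralModel:
    """Read a phyloFit-style text model (ALPHABET/BACKGROUND/RATE_MAT/TREE)."""
    text = open(path).read()
    bg = re.search(r"BACKGROUND:\s*([0-9.eE+\- ]+)", text)
    tree = re.search(r"TREE:\s*(\(.*?;)", text, re.S)
    mat = re.search(r"RATE_MAT:\s*\n((?:\s*[0-9.eE+\-]+[ \t]*)+)", text)
    if not (bg and tree and mat):
        raise FormatError(f"{path}: missing BACKGROUND, RATE_MAT or TREE stanza")
    pi = np.array([float(x) for x in bg.group(1).split()])
    values = [float(x) for x in mat.group(1).split()]
    if len(values) < 16:
        raise FormatError(f"{path}: RATE_MAT must have 16 entries")
    Q = np.array(values[:16]).reshape(4, 4)
    try:
        return NeutralModel(parse_newick(tree.group(1)), Q, pi)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_neutral_model(model: NeutralModel, path) -> None:
    with open(path, "w") as fh:
        fh.write("ALPHABET: A C G T\nORDER: 0\nSUBST_MOD: REV\n")
        fh.write("BACKGROUND: " + " ".join(f"{x:.8f}" for x in model.pi) + "\n")
        fh.write("RATE_MAT:\n")
        for row in model.Q:
            fh.write("  " + " ".join(f"{x:.8f}" for x in row) + "\n")
        fh.write("TREE: " + tree_to_newick(model.tree) + "\n")


# ---------------------------------------------------------------------------
# Simulation under the model (used by the synthetic-data generator)


def _adjacency(tree: TreeNode):
    nodes = list(tree.postorder())
    index = {id(n): i for i, n in enumerate(nodes)}
    adj: dict[int, list[tuple[int, float]]] = {i: [] for i in range(len(nodes))}
    for n in nodes:
        for c in n.children:
            i, j = index[id(n)], index[id(c)]
            adj[i].append((j, c.length))
            adj[j].append((i, c.length))
    return nodes, index, adj


def _sample_transition(P: np.ndarray, src: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    cum = P.cumsum(axis=1)
    u = rng.random(len(src))
    return (u[:, None] > cum[src]).sum(axis=1).astype(np.int8)


def simulate_columns(
    model: NeutralModel,
    scale: float,
    ncols: int,
    rng: np.random.Generator,
    anchor_leaf: str | None = None,
    anchor_states: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Simulate leaf states (codes 0-3) for ``ncols`` independent columns with
    every branch multiplied by ``scale``.

    With no anchor, root states are drawn from the equilibrium frequencies and
    evolved tipward. With ``anchor_leaf``/``anchor_states`` the simulation is
    conditioned on that leaf's sequence by traversing the tree outward from
    the leaf — exact for a reversible model whose anchor sequence is drawn
    from the equilibrium distribution.
    """
    nodes, index, adj = _adjacency(model.tree)
    states: dict[int, np.ndarray] = {}
    if anchor_leaf is None:
        start = index[id(nodes[-1])]  # root is last in postorder
        states[start] = _sample_transition(
            np.tile(model.pi, (4, 1)), np.zeros(ncols, dtype=np.int8), rng
        )
    else:
        leaf = next(n for n in nodes if n.name == anchor_leaf and not n.children)
        start = index[id(leaf)]
        if anchor_states is None:
            raise ValueError("anchor_states required with anchor_leaf")
        states[start] = np.asarray(anchor_states, dtype=np.int8)
    stack = [start]
    while stack:
        i = stack.pop()
        for j, length in adj[i]:
            if j in states:
                continue
            P = model.transition_matrix(length * scale)
            states[j] = _sample_transition(P, states[i], rng)
            stack.append(j)
    return {
        n.name: states[index[id(n)]] for n in nodes if not n.children
    }


def codes_to_seq(codes: np.ndarray) -> str:
    return "".join(BASES[c] if c < 4 else "N" for c in codes)
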