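"""Hypergeometric association tests, siRNA mapping/classification, feature
overlap counting, and assembly of the summary report tables.

The association question throughout is of the form "are NATs with property A
over- or under-represented among NATs with property B?", answered exactly
with the hypergeometric distribution: population N (all NATs of a dataset),
K successes (property A), a sample of n (property B), k with both.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .intervals import FeatureTrack, GenomicInterval, NatRecord, merge_intervals, overlap_bp


@dataclass(frozen=True)
class ContingencyCounts:
    N: int  # population size
    K: int  # population successes
    n: int  # sample size
    k: int  # sample successes

    def __post_init__(self) -> None:
        if not (0 <= self.K <= self.N and 0 <= self.n <= self.N):
            raise ValueError(f"invalid contingency counts {self}")
        if not (max(0, self.n + self.K - self.N) <= self.k <= min(self.K, self.n)):
            raise ValueError(f"invalid contingency counts {self}")


def _log_binom(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_logpmf(c: ContingencyCounts, i: np.ndarray) -> np.ndarray:
    return (
        _log_binom(c.K, i)
        + _log_binom(c.N - c.K, c.n - i)
        - _log_binom(c.N, c.n)
    )


def hypergeom_p(c: ContingencyCounts, tail: str = "enrichment") -> float:
    """Exact hypergeometric tail probability, summed in log space.

    ``enrichment``: P(X >= k); ``depletion``: P(X <= k).
    """
    lo = max(0, c.n + c.K - c.N)
    hi = min(c.K, c.n)
    if tail == "enrichment":
        i = np.arange(c.k, hi + 1)
    elif tail == "depletion":
        i = np.arange(lo, c.k + 1)
    else:
        raise ValueError("tail must be 'enrichment' or 'depletion'")
    if len(i) == 0:
        return 0.0
    return float(min(1.0, np.exp(logsumexp(hypergeom_logpmf(c, i)))))


def association_test(
    flags_a: Mapping[str, bool] | Sequence[bool],
    flags_b: Mapping[str, bool] | Sequence[bool],
) -> tuple[ContingencyCounts, float, float]:
    """Association of two boolean flags over the same NAT universe.

    Returns the counts (N = universe, K = sum A, n = sum B, k = sum A&B) and
    both tail p-values ``(counts, p_enrichment, p_depletion)``.
    """
    if isinstance(flags_a, Mapping) != isinstance(flags_b, Mapping):
        raise ValueError("flags must both be mappings or both sequences")
    if isinstance(flags_a, Mapping):
        if set(flags_a) != set(flags_b):
            raise ValueError("flag universes differ")
        keys = list(flags_a)
        a = np.array([bool(flags_a[x]) for x in keys])
        b = np.array([bool(flags_b[x]) for x in keys])
    else:
        if len(flags_a) != len(flags_b):
            raise ValueError("flag universes differ")
        a = np.asarray(flags_a, dtype=bool)
        b = np.asarray(flags_b, dtype=bool)
    c = ContingencyCounts(len(a), int(a.sum()), int(b.sum()), int((a & b).sum()))
    return c, hypergeom_p(c, "enrichment"), hypergeom_p(c, "depletion")


# ---------------------------------------------------------------------------
# siRNA mapping


@dataclass
class ReferenceSet:
    """Named sequences with NAT region labels for siRNA mapping.

    ``nat_regions[name]`` holds local-coordinate ``(start, end)`` lists for
    the NOLP and OLP parts of NAT references; ``locus[name]`` groups a NAT
    with its own sense gene so that same-locus reverse matches do not count
    as trans-acting.
    """

    seqs: dict[str, str]
    nat_regions: dict[str, dict[str, list[tuple[int, int]]]] = field(default_factory=dict)
    locus: dict[str, str] = field(default_factory=dict)

    def locus_of(self, name: str) -> str:
        return self.locus.get(name, name)


@dataclass
class SirnaMapping:
    read_id: str
    seq: str
    copies: int                 # redundant input reads collapsed onto this one
    reference: str | None
    offset: int | None
    orientation: str | None     # forward | reverse
    unique: bool
    compartment: str | None     # NOLP | OLP | other (unique NAT hits only)
    acting: str = "unassigned"  # cis | trans | unassigned


def _find_all(needle: str, hay: str) -> list[int]:
    out, pos = [], hay.find(needle)
    while pos != -1:
        out.append(pos)
        pos = hay.find(needle, pos + 1)
    return out


def _find_mismatch(needle: str, hay: str, max_mm: int) -> list[int]:
    n = len(needle)
    out = []
    for pos in range(len(hay) - n + 1):
        mm = 0
        for a, b in zip(needle, hay[pos:pos + n]):
            if a != b:
                mm += 1
                if mm > max_mm:
                    break
        if mm <= max_mm:
            out.append(pos)
    return out


def map_sirnas(
    reads: Mapping[str, str],
    references: ReferenceSet,
    max_mismatches: int = 0,
) -> tuple[list[SirnaMapping], int]:
    """Map short reads (18-30 nt) against the combined reference set.

    Reads are collapsed to a non-redundant sequence list first. A read is
    *unique* iff it has exactly one (reference, offset) match in forward
    orientation across all references; unique NAT hits get a NOLP/OLP
    compartment (by match midpoint) and a cis/trans label (trans iff the read
    also matches in reverse orientation on a transcribed region of another
    locus). Returns ``(mappings, n_skipped)``.
    """
    from .homology import revcomp

    by_seq: dict[str, list[str]] = {}
    skipped = 0
    for rid, seq in reads.items():
        seq = seq.upper()
        if not (18 <= len(seq) <= 30) or any(c not in "ACGT" for c in seq):
            skipped += 1
            continue
        by_seq.setdefault(seq, []).append(rid)

    mappings: list[SirnaMapping] = []
    for seq, rids in sorted(by_seq.items()):
        fwd: list[tuple[str, int]] = []
        rev: list[tuple[str, int]] = []
        rc = revcomp(seq)
        for name, ref in references.seqs.items():
            if max_mismatches == 0:
                fwd += [(name, p) for p in _find_all(seq, ref)]
                rev += [(name, p) for p in _find_all(rc, ref)]
            else:
                fwd += [(name, p) for p in _find_mismatch(seq, ref, max_mismatches)]
                rev += [(name, p) for p in _find_mismatch(rc, ref, max_mismatches)]
        unique = len(fwd) == 1
        m = SirnaMapping(rids[0], seq, len(rids), None, None, None, unique, None)
        if fwd:
            m.reference, m.offset = fwd[0]
            m.orientation = "forward"
        elif rev:
            m.reference, m.offset = rev[0]
            m.orientation = "reverse"
        if unique and m.reference in references.nat_regions:
            regions = references.nat_regions[m.reference]
            mid = m.offset + len(seq) // 2
            if any(s <= mid < e for s, e in regions.get("nolp", [])):
                m.compartment = "NOLP"
            elif any(s <= mid < e for s, e in regions.get("olp", [])):
                m.compartment = "OLP"
            else:
                m.compartment = "other"
            own = references.locus_of(m.reference)
            trans = any(references.locus_of(name) != own for name, _ in rev)
            m.acting = "trans" if trans else "cis"
        mappings.append(m)
    return mappings, skipped


def classify_sirna(
    mapping: SirnaMapping,
    reverse_matches: Iterable[str],
    references: ReferenceSet,
) -> str:
    """Cis/trans label for one unique forward NAT mapping given the reference
    names carrying reverse-orientation matches of the same read. Reverse
    matches within the NAT's own locus do not trigger the trans label."""
    if not mapping.unique or mapping.reference not in references.nat_regions:
        return "unassigned"
    own = references.locus_of(mapping.reference)
    for name in reverse_matches:
        if references.locus_of(name) != own:
            return "trans"
    return "cis"


# ---------------------------------------------------------------------------
# Feature overlap


def count_feature_overlap(
    nolps: Sequence[GenomicInterval], track: FeatureTrack, unit: str = "features"
) -> int:
    """``features``: number of distinct track intervals overlapping >=1 bp of
    any NOLP (a peak spanning two NOLPs counts once); ``bp``: total NOLP bp
    covered by the union of the track."""
    if unit == "features":
        return sum(
            1 for iv in track.intervals if any(overlap_bp(iv, q) > 0 for q in nolps)
        )
    if unit == "bp":
        union = merge_intervals(track.intervals) if track.intervals else []
        return sum(
            sum(overlap_bp(q, u) for u in union) for q in merge_intervals(nolps)
        ) if nolps else 0
    raise ValueError("unit must be 'features' or 'bp'")


# ---------------------------------------------------------------------------
# Report tables


def _star(p: float) -> str:
    return " †" if p < 0.05 else ""


def topology_table(records: list[NatRecord]) -> pd.DataFrame:
    """Per-topology tallies with conservation counts (Type 3 excluded from
    conservation, as it has no NOLP to test)."""
    rows = []
    total = len(records)
    n_cons_total = 0
    for t in (1, 2, 3, 4, 5):
        recs = [r for r in records if r.topology == t]
        if t == 3:
            cons = None
        else:
            cons = sum(1 for r in recs if r.conserved_phylo)
            n_cons_total += cons
        rows.append(
            {
                "type": t,
                "n": len(recs),
                "pct": round(100 * len(recs) / total) if total else 0,
                "n_conserved": cons if cons is not None else "--",
            }
        )
    rows.append({"type": "total", "n": total, "pct": 100 if total else 0,
                 "n_conserved": n_cons_total})
    return pd.DataFrame(rows)


def conservation_expression_table(records_by_dataset: dict[str, list[NatRecord]]) -> pd.DataFrame:
    """Cross-tab of sequence conservation (pairwise sister-genome and
    phylogenetic) against expression conservation, with hypergeometric
    association markers."""
    rows = []
    for dataset, records in records_by_dataset.items():
        universe = [r for r in records if r.topology != 3]
        n = len(universe)
        if n == 0:
            continue
        pairwise = {r.id: bool(r.conserved_pairwise) for r in universe}
        phylo = {r.id: bool(r.conserved_phylo) for r in universe}
        expr = {r.id: bool(r.expression_conserved) for r in universe}
        row = {"dataset": dataset, "total": n,
               "seq_conserved_pairwise": sum(pairwise.values()),
               "seq_conserved_phylo": sum(phylo.values()),
               "expression_conserved": sum(expr.values())}
        for label, flags in (("pairwise", pairwise), ("phylo", phylo)):
            try:
                c, p_enr, _ = association_test(flags, expr)
                row[f"both_{label}_expr"] = c.k
                row[f"p_assoc_{label}"] = f"{p_enr:.3g}{_star(p_enr)}"
            except ValueError:
                row[f"both_{label}_expr"] = "NA"
                row[f"p_assoc_{label}"] = "NA"
        rows.append(row)
    return pd.DataFrame(rows)


def chip_table(
    records_by_dataset: dict[str, list[NatRecord]],
    peaks: FeatureTrack,
) -> pd.DataFrame:
    """Distinct peak counts over all/conserved/expression-conserved NOLPs and
    a NAT-level hypergeometric enrichment p (universe = non-Type-3 NATs,
    successes = NATs with >=1 peak, sample = conserved NATs)."""
    rows = []
    for dataset, records in records_by_dataset.items():
        universe = [r for r in records if r.topology != 3 and r.nolps]
        if not universe:
            continue
        def peak_count(recs):
            nolps = [iv for r in recs for iv in r.nolps]
            return count_feature_overlap(nolps, peaks, "features") if nolps else 0

        has_peak = {r.id: any(
            overlap_bp(p, q) > 0 for p in peaks.intervals for q in r.nolps
        ) for r in universe}
        conserved = {r.id: bool(r.conserved_phylo) for r in universe}
        row = {
            "dataset": dataset,
            "peaks_all": peak_count(universe),
            "peaks_conserved": peak_count([r for r in universe if r.conserved_phylo]),
            "peaks_expression": peak_count([r for r in universe if r.expression_conserved]),
        }
        try:
            _, p_enr, _ = association_test(has_peak, conserved)
            row["p_enrichment_conserved"] = f"{p_enr:.3g}{_star(p_enr)}"
        except ValueError:
            row["p_enrichment_conserved"] = "NA"
        rows.append(row)
    return pd.DataFrame(rows)


def sirna_table(
    records_by_dataset: dict[str, list[NatRecord]],
    mappings_by_dataset: dict[str, list[SirnaMapping]],
) -> pd.DataFrame:
    """Unique-siRNA compartment tallies: NOLP, OLP, trans-acting NOLP, and the
    NOLP counts restricted to conserved / expression-conserved NATs."""
    rows = []
    for dataset, mappings in mappings_by_dataset.items():
        records = {r.id: r for r in records_by_dataset.get(dataset, [])}
        uniq = [m for m in mappings if m.unique and m.compartment in ("NOLP", "OLP")]
        nolp = [m for m in uniq if m.compartment == "NOLP"]
        rows.append(
            {
                "dataset": dataset,
                "unique_nolp": len(nolp),
                "unique_olp": sum(1 for m in uniq if m.compartment == "OLP"),
                "trans_nolp": sum(1 for m in nolp if m.acting == "trans"),
                "nolp_in_conserved": sum(
                    1 for m in nolp
                    if m.reference in records and records[m.reference].conserved_phylo
                ),
                "nolp_in_expression": sum(
                    1 for m in nolp
                    if m.reference in records and records[m.reference].expression_conserved
                ),
            }
        )
    return pd.DataFrame(rows)


def transposon_protein_table(
    records_by_dataset: dict[str, list[NatRecord]],
    transposons: FeatureTrack,
    protein_bp: dict[str, dict[str, int]] | None = None,
) -> pd.DataFrame:
    """NOLP bp covered by transposons (conserved vs all NOLPs) and, when
    supplied, bp covered by protein homology."""
    rows = []
    for dataset, records in records_by_dataset.items():
        universe = [r for r in records if r.topology != 3 and r.nolps]
        def bp(recs):
            nolps = [iv for r in recs for iv in r.nolps]
            return count_feature_overlap(nolps, transposons, "bp") if nolps else 0

        cons = [r for r in universe if r.conserved_phylo]
        row = {
            "dataset": dataset,
            "te_bp_conserved": bp(cons),
            "te_bp_total": bp(universe),
            "nolp_bp_conserved": sum(r.nolp_length() for r in cons),
            "nolp_bp_total": sum(r.nolp_length() for r in universe),
        }
        if protein_bp and dataset in protein_bp:
            row["protein_bp_conserved"] = protein_bp[dataset].get("conserved", 0)
            row["protein_bp_total"] = protein_bp[dataset].get("total", 0)
        rows.append(row)
    return pd.DataFrame(rows)


def build_report_tables(
    records_by_dataset: dict[str, list[NatRecord]],
    peaks: FeatureTrack | None = None,
    transposons: FeatureTrack | None = None,
    sirna_mappings: dict[str, list[SirnaMapping]] | None = None,
    protein_bp: dict[str, dict[str, int]] | None = None,
    null_results: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """Assemble every summary table the upstream stages support; stages whose
    inputs are missing are simply absent from the result."""
    tables: dict[str, pd.DataFrame] = {}
    for dataset, records in records_by_dataset.items():
        tables[f"topology_{dataset}"] = topology_table(records)
    tables["conservation_expression"] = conservation_expression_table(records_by_dataset)
    if peaks is not None:
        tables["chip_peaks"] = chip_table(records_by_dataset, peaks)
    if sirna_mappings is not None:
        tables["sirna"] = sirna_table(records_by_dataset, sirna_mappings)
    if transposons is not None:
        tables["transposon_protein"] = transposon_protein_table(
            records_by_dataset, transposons, protein_bp
        )
    if null_results is not None:
        tables["null_comparison"] = null_results
    return tables
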