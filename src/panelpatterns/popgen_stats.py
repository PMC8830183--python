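"""Per-variant population-genetic statistics for panel cohorts.

Cohort allele frequencies are read off the ternary genotype matrix
(alt-allele count = #het + 2·#hom over 2N chromosomes) and compared
per disease group against a gnomAD-style reference table with a
two-sided Fisher exact test and Benjamini–Hochberg correction.
Hardy–Weinberg equilibrium is tested with the exact conditional test
(enumeration over heterozygote counts given the allele counts), and
pairwise linkage disequilibrium between matrix rows is measured as the
squared Pearson correlation of genotype dosages (composite LD).

Missing genotypes are indistinguishable from hom-ref after the
presence/absence encoding, so the cohort allele number is fixed at 2N
for every variant; this slightly deflates cohort frequencies at sites
with genuine missingness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .variant_matrix import GenotypeMatrix, VariantKey

__all__ = [
    "ReferenceFrequencyTable",
    "AFTestResult",
    "HWEResult",
    "GroupSummary",
    "allele_frequency",
    "af_fisher_test",
    "benjamini_hochberg",
    "hwe_exact_test",
    "genotypic_r2",
    "group_af_screen",
    "screen_to_frame",
]


@dataclass
class ReferenceFrequencyTable:
    """Reference population allele counts: variant → (AC, AN).

    Lookup is by full variant key first, then by rsid, mirroring how
    panel variants are matched against gnomAD-style tables.
    """

    by_key: dict[VariantKey, tuple[int, int]] = field(default_factory=dict)
    by_rsid: dict[str, tuple[int, int]] = field(default_factory=dict)

    def add(self, key: VariantKey, ac: int, an: int) -> None:
        if an <= 0 or not (0 <= ac <= an):
            raise ValueError(f"invalid reference counts ac={ac}, an={an} for {key.label}")
        self.by_key[key] = (int(ac), int(an))
        if key.rsid:
            self.by_rsid[key.rsid] = (int(ac), int(an))

    def lookup(self, key: VariantKey) -> tuple[int, int] | None:
        hit = self.by_key.get(key)
        if hit is None and key.rsid:
            hit = self.by_rsid.get(key.rsid)
        return hit

    def __len__(self) -> int:
        return len(self.by_key)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ReferenceFrequencyTable":
        """Read a TSV with columns ``chrom pos ref alt rsid ac an`` (rsid optional)."""
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str, "rsid": str})
        table = cls()
        for row in df.itertuples(index=False):
            rsid = getattr(row, "rsid", None)
            if rsid is not None and (pd.isna(rsid) or rsid in ("", ".")):
                rsid = None
            key = VariantKey(str(row.chrom), int(row.pos), row.ref, row.alt, rsid)
            table.add(key, int(row.ac), int(row.an))
        return table

    def to_tsv(self, path: str | Path, header_comments: Sequence[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_comments:
                fh.write(f"#{line.lstrip('#')}\n")
            fh.write("chrom\tpos\tref\talt\trsid\tac\tan\n")
            for key in sorted(self.by_key, key=VariantKey.sort_key):
                ac, an = self.by_key[key]
                fh.write(f"{key.chrom}\t{key.pos}\t{key.ref}\t{key.alt}\t"
                         f"{key.rsid or '.'}\t{ac}\t{an}\n")


@dataclass
class AFTestResult:
    """Cohort-vs-reference allele-frequency comparison for one variant."""

    variant: VariantKey
    group: str
    cohort_ac: int
    cohort_an: int
    ref_ac: int
    ref_an: int
    odds_ratio: float
    p: float
    p_adj: float = float("nan")
    not_in_reference: bool = False

    @property
    def cohort_af(self) -> float:
        return self.cohort_ac / self.cohort_an

    @property
    def ref_af(self) -> float:
        return self.ref_ac / self.ref_an


@dataclass
class HWEResult:
    """Exact Hardy–Weinberg test outcome for one variant."""

    n_hom_ref: int
    n_het: int
    n_hom_alt: int
    p: float
    monomorphic: bool = False
    variant: VariantKey | None = None


@dataclass
class GroupSummary:
    """Per-disease-group variant counts (the Table-2-style summary)."""

    group: str
    n_samples: int
    mean_variants_per_patient: float
    n_unique_variants: int
    n_significant: int


def allele_frequency(row: np.ndarray | Sequence[int], n_samples: int | None = None
                     ) -> tuple[int, int, float]:
    """Alt-allele count, allele number, and frequency from a ternary row.

    ``ac = #het + 2·#hom-alt``; ``an = 2·n_samples`` (missing genotypes
    are encoded as 0, so the denominator is always the full cohort).
    """
    row = np.asarray(row)
    if n_samples is None:
        n_samples = row.size
    if row.size != n_samples:
        raise ValueError(f"row length {row.size} != n_samples {n_samples}")
    if not np.isin(row, (0, 1, 2)).all():
        raise ValueError("genotype values must be in {0, 1, 2}")
    ac = int(np.sum(row == 1) + 2 * np.sum(row == 2))
    an = 2 * int(n_samples)
    return ac, an, ac / an


def _fisher_two_sided_p(a: int, r1: int, r2: int, c1: int) -> float:
    """Two-sided Fisher p for cell ``a`` given margins (r1, r2, c1).

    Sums hypergeometric probabilities of all tables with the observed
    margins whose probability does not exceed the observed table's,
    with the relative tie tolerance 1 + 1e-7 that R's fisher.test uses
    (so exactly tied opposite-tail tables are always included despite
    floating-point rounding). Vectorized over the support, so large
    reference allele numbers cost only O(min(r1, c1)) work.
    """
    k = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    log_pmf = (gammaln(r1 + 1) - gammaln(k + 1) - gammaln(r1 - k + 1)
               + gammaln(r2 + 1) - gammaln(c1 - k + 1) - gammaln(r2 - c1 + k + 1))
    log_pmf -= log_pmf.max()
    pmf = np.exp(log_pmf)
    pmf /= pmf.sum()
    p_obs = pmf[np.searchsorted(k, a)]
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())


def af_fisher_test(cohort_ac: int, cohort_an: int, ref_ac: int, ref_an: int
                   ) -> tuple[float, float]:
    """Two-sided Fisher exact test of cohort vs reference allele counts.

    The 2×2 table is ``[[cohort_ac, cohort_an − cohort_ac],
    [ref_ac, ref_an − ref_ac]]`` (rows = population, columns = alt/ref
    allele). The two-sided p-value sums hypergeometric probabilities of
    tables no more likely than the observed one. The odds ratio is the
    unconditional sample OR, with a Haldane–Anscombe 0.5 continuity
    correction when any cell is zero.
    """
    for name, ac, an in (("cohort", cohort_ac, cohort_an), ("ref", ref_ac, ref_an)):
        if an <= 0:
            raise ValueError(f"{name}_an must be positive, got {an}")
        if not (0 <= ac <= an):
            raise ValueError(f"{name}_ac={ac} outside [0, {name}_an={an}]")
    p = _fisher_two_sided_p(int(cohort_ac), int(cohort_an), int(ref_an),
                            int(cohort_ac) + int(ref_ac))
    a, b = float(cohort_ac), float(cohort_an - cohort_ac)
    c, d = float(ref_ac), float(ref_an - ref_ac)
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds_ratio = (a * d) / (b * c)
    return odds_ratio, min(p, 1.0)


def benjamini_hochberg(pvals: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted p-values, returned in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int,
                   variant: VariantKey | None = None) -> HWEResult:
    """Exact conditional Hardy–Weinberg test from genotype counts.

    Conditions on the observed allele counts and sums the probabilities
    of all heterozygote counts (same parity, same allele totals) whose
    conditional probability does not exceed that of the observed count.
    A monomorphic variant returns p = 1 with the ``monomorphic`` flag.
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any((not isinstance(c, (int, np.integer))) or c < 0 for c in counts):
        raise ValueError(f"genotype counts must be non-negative integers, got {counts}")
    n = sum(counts)
    if n < 1:
        raise ValueError("need at least one genotype")
    n_alt = n_het + 2 * n_hom_alt
    n_ref = n_het + 2 * n_hom_ref
    if n_alt == 0 or n_ref == 0:
        return HWEResult(*counts, p=1.0, monomorphic=True, variant=variant)

    rare = min(n_alt, n_ref)
    hets = np.arange(rare % 2, rare + 1, 2)
    # log P(h | allele counts) up to a shared constant
    log_p = (hets * math.log(2)
             - gammaln((rare - hets) / 2 + 1)
             - gammaln(hets + 1)
             - gammaln((2 * n - rare - hets) / 2 + 1))
    log_p -= log_p.max()
    probs = np.exp(log_p)
    probs /= probs.sum()
    obs = probs[np.where(hets == n_het)[0][0]]
    p = float(probs[probs <= obs * (1 + 1e-12)].sum())
    return HWEResult(*counts, p=min(p, 1.0), variant=variant)


def genotypic_r2(row_i: np.ndarray | Sequence[int],
                 row_j: np.ndarray | Sequence[int]) -> float:
    """Composite LD between two variants: squared Pearson r of dosages."""
    x = np.asarray(row_i, dtype=float)
    y = np.asarray(row_j, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("rows must have equal length >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("LD undefined for a constant genotype row")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def group_af_screen(
    matrix: GenotypeMatrix,
    labels: Mapping[str, str],
    reference: ReferenceFrequencyTable,
    alpha: float = 0.05,
    default_ref_an: int = 100_000,
) -> tuple[list[AFTestResult], dict[str, GroupSummary]]:
    """Fisher + BH allele-frequency screen of each disease group.

    For each group the matrix is restricted to the group's columns,
    variants absent from the group are dropped, every remaining variant
    is tested against the reference (variants missing from the reference
    are tested with ``ref_ac = 0`` against ``default_ref_an`` chromosomes
    and flagged ``not_in_reference``), and BH correction is applied
    within the group's list of tested variants. The summary reports the
    mean per-patient call count, the number of distinct variants, and
    the number significant at ``p_adj < alpha``.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    missing = [s for s in matrix.samples if s not in labels]
    if missing:
        raise ValueError(f"samples without a group label: {missing}")
    groups: dict[str, list[str]] = {}
    for s in matrix.samples:
        groups.setdefault(labels[s], []).append(s)
    for g, members in groups.items():
        if not members:
            raise ValueError(f"group {g!r} is empty")

    results: list[AFTestResult] = []
    summaries: dict[str, GroupSummary] = {}
    for group in sorted(groups):
        sub = matrix.subset_samples(groups[group])
        n = len(sub.samples)
        per_patient = (sub.values > 0).sum(axis=0)
        group_results: list[AFTestResult] = []
        for i, key in enumerate(sub.variants):
            ac, an, _ = allele_frequency(sub.values[i, :], n)
            if ac == 0:
                continue
            hit = reference.lookup(key)
            if hit is None:
                ref_ac, ref_an, flagged = 0, default_ref_an, True
            else:
                (ref_ac, ref_an), flagged = hit, False
            odds_ratio, p = af_fisher_test(ac, an, ref_ac, ref_an)
            group_results.append(AFTestResult(
                variant=key, group=group, cohort_ac=ac, cohort_an=an,
                ref_ac=ref_ac, ref_an=ref_an, odds_ratio=odds_ratio, p=p,
                not_in_reference=flagged))
        adj = benjamini_hochberg([r.p for r in group_results])
        for r, pa in zip(group_results, adj):
            r.p_adj = float(pa)
        results.extend(group_results)
        summaries[group] = GroupSummary(
            group=group,
            n_samples=n,
            mean_variants_per_patient=float(per_patient.mean()),
            n_unique_variants=len(group_results),
            n_significant=int(sum(r.p_adj < alpha for r in group_results)),
        )
    return results, summaries


def screen_to_frame(results: Sequence[AFTestResult]) -> pd.DataFrame:
    """Tabulate AF-screen results, one row per (group, variant)."""
    return pd.DataFrame({
        "group": [r.group for r in results],
        "variant": [r.variant.label for r in results],
        "rsid": [r.variant.rsid or "." for r in results],
        "cohort_ac": [r.cohort_ac for r in results],
        "cohort_an": [r.cohort_an for r in results],
        "cohort_af": [r.cohort_af for r in results],
        "ref_ac": [r.ref_ac for r in results],
        "ref_an": [r.ref_an for r in results],
        "ref_af": [r.ref_af for r in results],
        "odds_ratio": [r.odds_ratio for r in results],
        "p": [r.p for r in results],
        "p_adj": [r.p_adj for r in results],
        "not_in_reference": [r.not_in_reference for r in results],
    })
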