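"""Variant-by-patient genotype matrices from per-sample VCF files.

Targeted gene panels report, per patient, a small VCF of single-nucleotide
variants and short indels. This module flattens a cohort of such files into a
single integer matrix: one row per variant seen in at least one patient, one
column per patient. Two encodings are supported —

* ``binary``: 0 = variant absent from the patient's VCF, 1 = present;
* ``ternary``: 0 = absent, 1 = heterozygous, 2 = homozygous for the
  alternate allele.

Variant identity is the raw VCF tuple ``(chrom, pos, ref, alt)``; no
left-alignment or indel trimming is performed (amplicon panel data are
called against a fixed design, so records are already comparable).
Multi-allelic records are split into one row per alternate allele.
Missing genotypes and homozygous-reference calls both encode as 0.
"""

from __future__ import annotations

import io
import logging
import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

__all__ = [
    "VariantKey",
    "SampleCallSet",
    "GenotypeMatrix",
    "phred_to_error_rate",
    "parse_vcf",
    "build_matrix",
]

_ALLELE_RE = re.compile(r"^[ACGT]+$")


def phred_to_error_rate(q: float) -> float:
    """Convert a Phred quality score to the base-call error probability.

    Phred Q relates to the error rate p by ``Q = -10 log10(p)``, so
    ``p = 10**(-Q/10)``. The conventional Q30 filter admits at most a
    0.1% error rate.

    Parameters
    ----------
    q : float
        Phred-scaled quality, ``q >= 0`` and finite.

    Returns
    -------
    float
        Error probability in ``(0, 1]``.
    """
    q = float(q)
    if not math.isfinite(q) or q < 0:
        raise ValueError(f"Phred quality must be finite and non-negative, got {q!r}")
    return 10.0 ** (-q / 10.0)


@dataclass(frozen=True)
class VariantKey:
    """Identity of a variant: VCF coordinates and alleles.

    Equality and hashing use ``(chrom, pos, ref, alt)`` only; ``rsid`` is
    carried for display and tag-SNP lookup but never participates in
    identity. Positions are 1-based as in the VCF standard.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    rsid: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not isinstance(self.pos, (int, np.integer)) or self.pos <= 0:
            raise ValueError(f"pos must be a positive integer, got {self.pos!r}")
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if not _ALLELE_RE.match(allele or ""):
                raise ValueError(
                    f"{name} allele {allele!r} is not a non-empty ACGT string "
                    "(symbolic and breakend alleles are not supported)"
                )
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical ({self.ref!r})")

    @property
    def label(self) -> str:
        """``chrom:pos:ref:alt`` with the rsid appended when known."""
        base = f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"
        return f"{base}:{self.rsid}" if self.rsid else base

    def sort_key(self) -> tuple:
        return (_chrom_rank(self.chrom), self.pos, self.ref, self.alt)

    @classmethod
    def from_label(cls, label: str) -> "VariantKey":
        parts = label.split(":")
        if len(parts) not in (4, 5):
            raise ValueError(f"cannot parse variant label {label!r}")
        chrom, pos, ref, alt = parts[:4]
        rsid = parts[4] if len(parts) == 5 and parts[4] else None
        return cls(chrom, int(pos), ref, alt, rsid)


def _chrom_rank(chrom: str) -> tuple:
    """Natural chromosome order: numeric first, then X, Y, MT, then others."""
    c = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if c.isdigit():
        return (0, int(c), "")
    special = {"X": 23, "Y": 24, "M": 25, "MT": 25}
    if c.upper() in special:
        return (0, special[c.upper()], "")
    return (1, 0, c)


@dataclass
class SampleCallSet:
    """All alt-genotype calls of one patient: variant key → zygosity 1|2."""

    sample_id: str
    calls: dict[VariantKey, int] = field(default_factory=dict)
    n_skipped: int = 0

    def __post_init__(self) -> None:
        bad = {k: z for k, z in self.calls.items() if z not in (1, 2)}
        if bad:
            raise ValueError(f"zygosity codes must be 1 or 2, got {bad}")

    def __len__(self) -> int:
        return len(self.calls)


def parse_vcf(
    path: str | Path,
    min_qual: float = 30.0,
    sample_id: str | None = None,
) -> SampleCallSet:
    """Read one single-sample VCF into a :class:`SampleCallSet`.

    Records with ``QUAL`` below ``min_qual`` (or missing) are dropped.
    Multi-allelic records are split into one key per alternate allele; the
    zygosity of each allele is the number of genotype haplotypes carrying
    it (0/1 → het for allele 1; 1/2 → het for both; 2/2 → hom for allele
    2). Hom-ref and fully missing genotypes produce no call. Records whose
    genotype cannot be interpreted are skipped with a warning and counted
    in ``n_skipped``.

    Parameters
    ----------
    path : str or Path
        Single-sample VCF, plain text or bgzipped.
    min_qual : float
        Phred QUAL threshold; default 30 (≤ 0.1% error rate).
    sample_id : str, optional
        Override for the sample name; defaults to the VCF sample column,
        falling back to the file name stem.
    """
    path = Path(path)
    if min_qual < 0 or not math.isfinite(min_qual):
        raise ValueError(f"min_qual must be finite and >= 0, got {min_qual}")
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare Exception on bad files
        raise OSError(f"cannot read VCF {path}: {exc}") from exc
    try:
        if len(vcf.samples) > 1:
            raise ValueError(
                f"{path} is a multi-sample VCF ({len(vcf.samples)} samples); "
                "panelpatterns expects one file per patient"
            )
        sid = sample_id or (vcf.samples[0] if vcf.samples else path.name.split(".")[0])
        calls: dict[VariantKey, int] = {}
        n_skipped = 0
        for rec in vcf:
            qual = rec.QUAL
            if qual is None or qual < min_qual:
                continue
            try:
                gt = rec.genotypes[0]
                alleles = [a for a in gt[:-1] if a is not None]
            except (IndexError, TypeError, ValueError):
                n_skipped += 1
                warnings.warn(f"{path}: malformed GT at {rec.CHROM}:{rec.POS}, record skipped")
                continue
            if not alleles:
                n_skipped += 1
                warnings.warn(f"{path}: empty GT at {rec.CHROM}:{rec.POS}, record skipped")
                continue
            for alt_index, alt in enumerate(rec.ALT, start=1):
                dosage = sum(1 for a in alleles if a == alt_index)
                if dosage == 0:
                    continue
                try:
                    key = VariantKey(rec.CHROM, rec.POS, rec.REF, alt,
                                     rec.ID if rec.ID not in (None, ".") else None)
                except ValueError:
                    n_skipped += 1
                    warnings.warn(
                        f"{path}: unsupported alleles at {rec.CHROM}:{rec.POS} "
                        f"({rec.REF}>{alt}), record skipped"
                    )
                    continue
                zyg = 2 if dosage >= 2 else 1
                if key in calls:
                    warnings.warn(f"{path}: duplicate record for {key.label}; keeping first")
                    continue
                calls[key] = zyg
        if n_skipped:
            logger.info("parse_vcf(%s): skipped %d malformed records", path, n_skipped)
        return SampleCallSet(sample_id=sid, calls=calls, n_skipped=n_skipped)
    finally:
        vcf.close()


@dataclass
class GenotypeMatrix:
    """Variants × samples integer matrix with row/column identifiers.

    Rows are sorted by (chrom, pos, ref, alt) with natural chromosome
    order; columns follow the input order of the cohort. ``mode`` is
    ``"binary"`` ({0,1}) or ``"ternary"`` ({0,1,2}).
    """

    variants: list[VariantKey]
    samples: list[str]
    values: np.ndarray
    mode: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.mode not in ("binary", "ternary"):
            raise ValueError(f"mode must be 'binary' or 'ternary', got {self.mode!r}")
        if self.values.shape != (len(self.variants), len(self.samples)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.variants)} variants x {len(self.samples)} samples"
            )
        hi = 1 if self.mode == "binary" else 2
        if self.values.size and (self.values.min() < 0 or self.values.max() > hi):
            raise ValueError(f"values out of range for mode={self.mode}")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def binarize(self) -> "GenotypeMatrix":
        """Presence/absence view: every nonzero entry becomes 1."""
        if self.mode == "binary":
            return GenotypeMatrix(list(self.variants), list(self.samples),
                                  self.values.copy(), "binary")
        return GenotypeMatrix(list(self.variants), list(self.samples),
                              (self.values > 0).astype(np.int8), "binary")

    # -- lookup -----------------------------------------------------------

    def index_of(self, key: "VariantKey | str") -> int:
        """Row index of a variant, by key, rsid, or ``chrom:pos:ref:alt`` label."""
        if isinstance(key, VariantKey):
            for i, v in enumerate(self.variants):
                if v == key:
                    return i
            raise KeyError(f"variant {key.label} not in matrix")
        for i, v in enumerate(self.variants):
            if v.rsid == key:
                return i
        try:
            return self.index_of(VariantKey.from_label(key))
        except (ValueError, KeyError):
            raise KeyError(f"variant {key!r} not in matrix (by rsid or label)") from None

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        col = {s: j for j, s in enumerate(self.samples)}
        missing = [s for s in sample_ids if s not in col]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        idx = [col[s] for s in sample_ids]
        return GenotypeMatrix(list(self.variants), list(sample_ids),
                              self.values[:, idx].copy(), self.mode)

    def drop_variants(self, rows: Iterable[int]) -> "GenotypeMatrix":
        drop = set(rows)
        keep = [i for i in range(len(self.variants)) if i not in drop]
        if not keep:
            raise ValueError("dropping every variant leaves an empty matrix")
        return GenotypeMatrix([self.variants[i] for i in keep], list(self.samples),
                              self.values[keep, :].copy(), self.mode)

    # -- serialization ----------------------------------------------------

    def to_tsv(self, path: str | Path, header_comments: Sequence[str] = ()) -> None:
        """Write the matrix as TSV; first column is the variant label."""
        with open(path, "w") as fh:
            for line in header_comments:
                fh.write(f"#{line.lstrip('#')}\n")
            fh.write(f"#mode={self.mode}\n")
            df = pd.DataFrame(self.values, columns=self.samples)
            df.insert(0, "variant", [v.label for v in self.variants])
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenotypeMatrix":
        mode = None
        body: list[str] = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    if line.startswith("#mode="):
                        mode = line.strip().split("=", 1)[1]
                    continue
                body.append(line)
        if mode is None:
            raise ValueError(f"{path}: missing '#mode=' header line")
        df = pd.read_csv(io.StringIO("".join(body)), sep="\t", dtype={"variant": str})
        variants = [VariantKey.from_label(lbl) for lbl in df["variant"]]
        samples = [str(c) for c in df.columns[1:]]
        values = df.iloc[:, 1:].to_numpy(dtype=np.int8)
        return cls(variants, samples, values, mode)


def build_matrix(
    callsets: Sequence[SampleCallSet],
    mode: str = "binary",
) -> GenotypeMatrix:
    """Assemble per-patient call sets into one :class:`GenotypeMatrix`.

    Rows are the sorted union of every variant observed in at least one
    patient; a cell is 0 when the patient's VCF lacks the variant,
    otherwise 1 (binary) or the zygosity code (ternary). Column order is
    the input order of ``callsets``.
    """
    if not callsets:
        raise ValueError("need at least one call set")
    if mode not in ("binary", "ternary"):
        raise ValueError(f"mode must be 'binary' or 'ternary', got {mode!r}")
    sample_ids = [cs.sample_id for cs in callsets]
    if len(set(sample_ids)) != len(sample_ids):
        dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise ValueError(f"duplicate sample ids: {dupes}")

    # union of keys; prefer a non-None rsid when call sets disagree
    rsids: dict[VariantKey, str | None] = {}
    for cs in callsets:
        for key in cs.calls:
            if key not in rsids or (rsids[key] is None and key.rsid is not None):
                rsids[key] = key.rsid
    if not rsids:
        raise ValueError("no variants in any call set")
    variants = sorted(
        (VariantKey(k.chrom, k.pos, k.ref, k.alt, rsids[k]) for k in rsids),
        key=VariantKey.sort_key,
    )
    row = {v: i for i, v in enumerate(variants)}
    values = np.zeros((len(variants), len(callsets)), dtype=np.int8)
    for j, cs in enumerate(callsets):
        for key, zyg in cs.calls.items():
            values[row[key], j] = zyg if mode == "ternary" else 1
    return GenotypeMatrix(variants, sample_ids, values, mode)
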