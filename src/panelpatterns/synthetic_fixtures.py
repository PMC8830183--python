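"""Synthetic multi-group panel cohorts with planted, recoverable structure.

The generator emulates the statistical shape of a targeted-panel dementia
cohort: three phenotype groups (default 46/40/26 patients, two of which
form one disease entity), ~1000 polymorphic background variants drawn at
reference allele frequencies under Hardy–Weinberg, one fully penetrant
causal variant exclusive to each genetic subgroup, a block of perfectly
linked SNPs riding on a two-haplotype system (the MAPT H1/H2 situation),
one SNP sampled out of Hardy–Weinberg proportions, and a handful of
variants whose cohort frequency is shifted away from the reference in one
group. Every planted fact is recorded in a truth dictionary so tests can
assert recovery.

Genotypes are independent across variants except inside the LD block;
there is no genome-wide LD model, sequencing-error model, or realistic
site-frequency spectrum — the cohorts exist to exercise the pipeline's
inference, not to imitate real panels beyond their group structure.

Causal variants are deliberately left out of the reference table so the
allele-frequency screen exercises its "not in reference" path, mirroring
panel variants absent from gnomAD.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .popgen_stats import ReferenceFrequencyTable
from .variant_matrix import GenotypeMatrix, SampleCallSet, VariantKey

__all__ = [
    "LDBlockSpec",
    "HWEViolationSpec",
    "BackgroundSpec",
    "AFShiftSpec",
    "SyntheticCohortSpec",
    "SyntheticCohort",
    "simulate_cohort",
    "write_cohort",
    "disease_labels",
    "PlantedModule",
    "NetworkFixture",
    "simulate_network_fixture",
    "write_network_fixture",
    "DEFAULT_DISEASE_MAP",
]

DEFAULT_DISEASE_MAP = {"sAD": "AD", "V210I": "CJD", "E200K": "CJD"}


@dataclass
class LDBlockSpec:
    """A set of SNPs in perfect LD: every alt allele rides the minor haplotype."""

    variants: list[VariantKey]
    h2_freq: float = 0.22
    names: tuple[str, str] = ("H1", "H2")

    def validate(self) -> None:
        if not 0 < self.h2_freq < 1:
            raise ValueError(f"ld_block.h2_freq must be in (0,1), got {self.h2_freq}")
        if len(self.variants) < 2:
            raise ValueError("ld_block.variants needs at least 2 SNPs")


@dataclass
class HWEViolationSpec:
    """One SNP drawn from f-inflated genotype frequencies.

    Genotype probabilities are ``(p² + f·p·q, 2pq(1 − f), q² + f·p·q)``
    for alt frequency q; negative f gives heterozygote excess.
    """

    key: VariantKey
    af: float = 0.35
    f: float = -0.5

    def validate(self) -> None:
        if not 0 < self.af < 1:
            raise ValueError(f"hwe_violation.af must be in (0,1), got {self.af}")
        if not -1 < self.f < 1:
            raise ValueError(f"hwe_violation.f must be in (-1,1), got {self.f}")
        p, q = 1 - self.af, self.af
        if min(p * p + self.f * p * q, q * q + self.f * p * q) < 0:
            raise ValueError("hwe_violation.f incompatible with af "
                             "(negative genotype frequency)")


@dataclass
class BackgroundSpec:
    """Unstructured polymorphic background drawn at reference frequencies."""

    n_variants: int = 1000
    beta_a: float = 0.25
    beta_b: float = 8.0
    af_floor: float = 0.005
    af_ceiling: float = 0.5

    def validate(self) -> None:
        if self.n_variants < 0:
            raise ValueError(f"background.n_variants must be >= 0, got {self.n_variants}")
        if not 0 < self.af_floor <= self.af_ceiling <= 0.5:
            raise ValueError("background AF bounds must satisfy "
                             "0 < floor <= ceiling <= 0.5")


@dataclass
class AFShiftSpec:
    """A variant whose AF in one group departs from its reference AF."""

    group: str
    key: VariantKey
    ref_af: float = 0.01
    cohort_af: float = 0.30

    def validate(self) -> None:
        for name, v in (("ref_af", self.ref_af), ("cohort_af", self.cohort_af)):
            if not 0 < v < 1:
                raise ValueError(f"af_shift.{name} must be in (0,1), got {v}")


@dataclass
class SyntheticCohortSpec:
    """Everything the cohort generator plants, plus the seed.

    ``causal_variants`` maps group → list of (variant, penetrance):
    each listed variant is heterozygous in a member of its group with
    probability = penetrance and absent from every other group.
    Fully penetrant entries model disease-causing mutations; penetrance
    < 1 models partial modifiers.
    """

    group_sizes: dict[str, int]
    causal_variants: dict[str, list[tuple[VariantKey, float]]] = field(default_factory=dict)
    ld_block: LDBlockSpec | None = None
    hwe_violation: HWEViolationSpec | None = None
    background: BackgroundSpec = field(default_factory=BackgroundSpec)
    af_shifts: list[AFShiftSpec] = field(default_factory=list)
    ref_an: int = 100_000
    seed: int = 0

    def validate(self) -> None:
        if not self.group_sizes:
            raise ValueError("group_sizes is empty")
        for g, n in self.group_sizes.items():
            if n < 2:
                raise ValueError(f"group_sizes[{g!r}] must be >= 2, got {n}")
        for g in self.causal_variants:
            if g not in self.group_sizes:
                raise ValueError(f"causal_variants group {g!r} not in group_sizes")
            for key, pen in self.causal_variants[g]:
                if not 0 < pen <= 1:
                    raise ValueError(
                        f"causal_variants[{g!r}] penetrance must be in (0,1], got {pen}")
        for s in self.af_shifts:
            if s.group not in self.group_sizes:
                raise ValueError(f"af_shifts group {s.group!r} not in group_sizes")
            s.validate()
        if self.ld_block is not None:
            self.ld_block.validate()
        if self.hwe_violation is not None:
            self.hwe_violation.validate()
        self.background.validate()
        if self.ref_an <= 0:
            raise ValueError(f"ref_an must be positive, got {self.ref_an}")

    @classmethod
    def default(cls, seed: int = 0, n_background: int = 1000) -> "SyntheticCohortSpec":
        """The study-shaped default: 46 sAD + 40 V210I + 26 E200K patients.

        Two fully penetrant causal variants (one per CJD subgroup), a
        6-SNP perfectly linked block at minor-haplotype frequency 0.22
        tagged by rs1052553/rs1800547, one heterozygote-excess SNP, and
        five AF-shifted variants per group (reference AF 0.01, cohort AF
        0.30 in the shifted group).
        """
        block = [
            VariantKey("17", 44_051_846 + 1000 * i, "A", "G",
                       rsid=("rs1052553", "rs1800547", "rs11575896")[i] if i < 3
                       else f"rsBLOCK{i}")
            for i in range(6)
        ]
        shifts = []
        groups = ("sAD", "V210I", "E200K")
        for gi, g in enumerate(groups):
            for i in range(5):
                shifts.append(AFShiftSpec(
                    group=g,
                    key=VariantKey("2", 10_000_000 + 10_000 * gi + 100 * i, "C", "T"),
                    ref_af=0.01, cohort_af=0.30))
        return cls(
            group_sizes={"sAD": 46, "V210I": 40, "E200K": 26},
            causal_variants={
                "V210I": [(VariantKey("20", 4_680_251, "G", "A"), 1.0)],
                "E200K": [(VariantKey("20", 4_680_404, "G", "A"), 1.0)],
            },
            ld_block=LDBlockSpec(variants=block, h2_freq=0.22),
            hwe_violation=HWEViolationSpec(
                key=VariantKey("19", 15_302_000, "T", "A", rsid="rs11670823"),
                af=0.35, f=-0.5),
            background=BackgroundSpec(n_variants=n_background),
            af_shifts=shifts,
            seed=seed,
        )


    @classmethod
    def perfect_separation(cls, seed: int = 0,
                           n_background: int = 1000) -> "SyntheticCohortSpec":
        """Two fully penetrant causal variants over pure background.

        The default cohort minus the AF-shifted variants: once the two
        CJD subgroups are collapsed to one disease label, the causal
        variants are the only group-separating signal, so a correct
        classifier must split on exactly those two rows.
        """
        spec = cls.default(seed=seed, n_background=n_background)
        spec.af_shifts = []
        return spec

    @classmethod
    def with_modifiers(cls, seed: int = 0, penetrance: float = 0.8,
                       n_background: int = 1000) -> "SyntheticCohortSpec":
        """Perfect-separation cohort plus one partial modifier per CJD subgroup.

        With the causal variants masked, the modifiers are the only
        disease-associated signal left, so test accuracy drops below 1
        but stays above the majority-class fraction.
        """
        spec = cls.perfect_separation(seed=seed, n_background=n_background)
        spec.causal_variants["V210I"].append(
            (VariantKey("21", 26_000_000, "A", "T"), penetrance))
        spec.causal_variants["E200K"].append(
            (VariantKey("21", 26_100_000, "G", "A"), penetrance))
        return spec

    @classmethod
    def null_screen(cls, seed: int = 0, n_variants: int = 500,
                    n_samples: int = 40) -> "SyntheticCohortSpec":
        """One unlabeled-structure group drawn exactly at reference AFs.

        Every allele-frequency discovery on such a cohort is a false
        discovery; used to measure the realized FDR of the screen.
        """
        return cls(
            group_sizes={"null": n_samples},
            background=BackgroundSpec(n_variants=n_variants),
            seed=seed,
        )


@dataclass
class SyntheticCohort:
    """A realized cohort: ternary matrix, labels, reference table, truth."""

    spec: SyntheticCohortSpec
    matrix: GenotypeMatrix
    labels: dict[str, str]
    reference: ReferenceFrequencyTable
    truth: dict

    @property
    def samples(self) -> list[str]:
        return self.matrix.samples

    def callsets(self) -> list[SampleCallSet]:
        """Per-sample call sets equivalent to the matrix columns."""
        out = []
        for j, sid in enumerate(self.matrix.samples):
            calls = {self.matrix.variants[i]: int(z)
                     for i, z in enumerate(self.matrix.values[:, j]) if z}
            out.append(SampleCallSet(sample_id=sid, calls=calls))
        return out


def simulate_cohort(spec: SyntheticCohortSpec) -> SyntheticCohort:
    """Draw one cohort realization from a :class:`SyntheticCohortSpec`.

    Background and shifted genotypes are binomial(2, af) per sample
    (Hardy–Weinberg); causal variants are heterozygous in carriers;
    LD-block zygosities equal the sample's minor-haplotype dosage; the
    HWE-violation SNP is drawn from its f-inflated genotype frequencies.
    Variants observed in nobody are dropped (they cannot appear in a
    VCF-derived matrix); the number dropped is recorded in the truth.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    samples: list[str] = []
    groups: list[str] = []
    for g, n in spec.group_sizes.items():
        for i in range(n):
            samples.append(f"{g}_{i + 1:03d}")
            groups.append(g)
    group_arr = np.array(groups)
    n_samples = len(samples)

    rows: list[tuple[VariantKey, np.ndarray]] = []
    reference = ReferenceFrequencyTable()
    truth: dict = {
        "seed": spec.seed,
        "group_sizes": dict(spec.group_sizes),
        "samples": {s: g for s, g in zip(samples, groups)},
        "causal": {}, "shifted": {}, "ld_block": None, "hwe": None,
    }

    def ref_add(key: VariantKey, af: float) -> None:
        reference.add(key, int(round(af * spec.ref_an)), spec.ref_an)

    # background: binomial(2, af) everywhere
    bg = spec.background
    if bg.n_variants:
        afs = np.clip(rng.beta(bg.beta_a, bg.beta_b, size=bg.n_variants),
                      bg.af_floor, bg.af_ceiling)
        geno = rng.binomial(2, afs[:, None], size=(bg.n_variants, n_samples))
        for i in range(bg.n_variants):
            key = VariantKey(str(1 + i % 22), 1_000_000 + 137 * (i // 22 + 1) + i,
                             "G", "C")
            ref_add(key, float(afs[i]))
            rows.append((key, geno[i].astype(np.int8)))

    # group-shifted variants
    for shift in spec.af_shifts:
        af_vec = np.where(group_arr == shift.group, shift.cohort_af, shift.ref_af)
        g = rng.binomial(2, af_vec).astype(np.int8)
        ref_add(shift.key, shift.ref_af)
        rows.append((shift.key, g))
        truth["shifted"].setdefault(shift.group, []).append(shift.key.label)

    # causal / modifier variants: het in carriers, absent elsewhere
    for g, entries in spec.causal_variants.items():
        for key, penetrance in entries:
            carrier = (group_arr == g) & (rng.random(n_samples) < penetrance)
            rows.append((key, carrier.astype(np.int8)))
            truth["causal"].setdefault(g, []).append(
                {"variant": key.label, "penetrance": penetrance})
            # deliberately absent from the reference table (gnomAD-novel)

    # LD block: all SNPs carry the minor haplotype dosage
    if spec.ld_block is not None:
        h = rng.binomial(2, spec.ld_block.h2_freq, size=n_samples).astype(np.int8)
        for key in spec.ld_block.variants:
            ref_add(key, spec.ld_block.h2_freq)
            rows.append((key, h.copy()))
        truth["ld_block"] = {
            "variants": [k.label for k in spec.ld_block.variants],
            "h2_freq": spec.ld_block.h2_freq,
            "names": list(spec.ld_block.names),
            "dosage": {s: int(d) for s, d in zip(samples, h)},
        }

    # HWE-violation SNP
    if spec.hwe_violation is not None:
        hv = spec.hwe_violation
        p, q, f = 1 - hv.af, hv.af, hv.f
        probs = np.array([p * p + f * p * q, 2 * p * q * (1 - f), q * q + f * p * q])
        g = rng.choice(3, size=n_samples, p=probs / probs.sum()).astype(np.int8)
        ref_add(hv.key, hv.af)
        rows.append((hv.key, g))
        truth["hwe"] = {"variant": hv.key.label, "af": hv.af, "f": hv.f}

    observed = [(k, v) for k, v in rows if v.any()]
    truth["n_dropped_monomorphic"] = len(rows) - len(observed)
    if not observed:
        raise ValueError("cohort realization contains no observed variants")
    observed.sort(key=lambda kv: kv[0].sort_key())
    matrix = GenotypeMatrix(
        variants=[k for k, _ in observed],
        samples=samples,
        values=np.vstack([v for _, v in observed]),
        mode="ternary",
    )
    return SyntheticCohort(spec=spec, matrix=matrix,
                           labels=dict(zip(samples, groups)),
                           reference=reference, truth=truth)


def disease_labels(cohort: SyntheticCohort,
                   mapping: Mapping[str, str] | None = None) -> dict[str, str]:
    """Collapse group labels to disease labels (default: CJD subgroups merge)."""
    mapping = dict(mapping or DEFAULT_DISEASE_MAP)
    return {s: mapping.get(g, g) for s, g in cohort.labels.items()}


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path,
                 qual: float = 60.0) -> Path:
    """Serialize a cohort: per-sample VCFs, labels TSV, reference TSV, truth JSON.

    Output is deterministic (no timestamps), so identical specs produce
    byte-identical fixture trees.
    """
    out = Path(out_dir)
    vcf_dir = out / "vcfs"
    vcf_dir.mkdir(parents=True, exist_ok=True)
    chroms = sorted({v.chrom for v in cohort.matrix.variants},
                    key=lambda c: VariantKey(c, 1, "A", "G").sort_key())
    header = ["##fileformat=VCFv4.2", "##source=panelpatterns-synthetic"]
    header += [f"##contig=<ID={c}>" for c in chroms]
    header.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for j, sid in enumerate(cohort.matrix.samples):
        lines = list(header)
        lines.append(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sid}")
        for i, key in enumerate(cohort.matrix.variants):
            z = cohort.matrix.values[i, j]
            if z == 0:
                continue
            gt = "0/1" if z == 1 else "1/1"
            lines.append(f"{key.chrom}\t{key.pos}\t{key.rsid or '.'}\t{key.ref}"
                         f"\t{key.alt}\t{qual:g}\tPASS\t.\tGT\t{gt}")
        (vcf_dir / f"{sid}.vcf").write_text("\n".join(lines) + "\n")
    with open(out / "labels.tsv", "w") as fh:
        fh.write("sample_id\tgroup\n")
        for s in cohort.matrix.samples:
            fh.write(f"{s}\t{cohort.labels[s]}\n")
    cohort.reference.to_tsv(out / "reference_af.tsv")
    with open(out / "truth.json", "w") as fh:
        json.dump(cohort.truth, fh, indent=1, sort_keys=True)
    return out


# ---------------------------------------------------------------------------
# network fixtures


@dataclass
class PlantedModule:
    """A clique of genes around a designated hub, sharing one term."""

    name: str
    genes: list[str]
    hub: str
    term: str
    extra_spokes: int = 10


@dataclass
class NetworkFixture:
    """Edge lists (per source), annotation maps, and the planted truth."""

    edge_lists: dict[str, list[tuple[str, str]]]
    annotation: dict[str, set[str]]
    term_names: dict[str, str]
    truth: dict


def simulate_network_fixture(
    n_genes: int = 60,
    planted_modules: Sequence[PlantedModule] | None = None,
    seed: int = 0,
    edge_p: float = 0.05,
    n_random_terms: int = 6,
) -> NetworkFixture:
    """Random interactome plus planted hub-centred cliques and terms.

    The background is an Erdős–Rényi graph over ``n_genes`` symbols.
    Each planted module becomes a clique (genes + hub); the hub gains
    ``extra_spokes`` additional background partners, so it is the
    highest-degree member of the module's 1-hop subnetwork. The module's
    term annotates exactly its genes and hub; every gene also receives
    one or two random decoy terms. Edges are split across two source
    "databases" with a small overlap so provenance merging is exercised.
    """
    rng = np.random.default_rng(seed)
    modules = list(planted_modules) if planted_modules is not None else [
        PlantedModule("moduleA", [f"MA{i:02d}" for i in range(5)], "HUBA", "T:A"),
        PlantedModule("moduleB", [f"MB{i:02d}" for i in range(5)], "HUBB", "T:B"),
    ]
    background_genes = [f"BG{i:03d}" for i in range(n_genes)]
    for m in modules:
        if m.extra_spokes > n_genes:
            raise ValueError(f"module {m.name}: extra_spokes > n_genes")

    edges: set[tuple[str, str]] = set()

    def add(a: str, b: str) -> None:
        if a != b:
            edges.add(tuple(sorted((a, b))))

    for i in range(n_genes):
        for j in range(i + 1, n_genes):
            if rng.random() < edge_p:
                add(background_genes[i], background_genes[j])
    for m in modules:
        members = [*m.genes, m.hub]
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                add(members[i], members[j])
        spokes = rng.choice(n_genes, size=m.extra_spokes, replace=False)
        for s in spokes:
            add(m.hub, background_genes[s])

    ordered = sorted(edges)
    edge_lists: dict[str, list[tuple[str, str]]] = {"dbA": [], "dbB": []}
    for i, e in enumerate(ordered):
        edge_lists["dbA" if i % 2 == 0 else "dbB"].append(e)
    edge_lists["dbB"].extend(ordered[:5])  # overlap: provenance union

    term_pool = [f"T:R{i}" for i in range(n_random_terms)]
    annotation: dict[str, set[str]] = {}
    term_names = {"T:A": "planted module A process",
                  "T:B": "planted module B process"}
    for t in term_pool:
        term_names[t] = f"decoy process {t[-1]}"
    all_genes = background_genes + [g for m in modules for g in (*m.genes, m.hub)]
    for g in all_genes:
        picks = rng.choice(n_random_terms, size=int(rng.integers(1, 3)),
                           replace=False)
        annotation[g] = {term_pool[i] for i in picks}
    for m in modules:
        for g in (*m.genes, m.hub):
            annotation[g].add(m.term)

    truth = {
        "seed": seed,
        "n_genes": n_genes,
        "edge_p": edge_p,
        "modules": [{"name": m.name, "genes": m.genes, "hub": m.hub,
                     "seeds": [*m.genes, m.hub], "term": m.term}
                    for m in modules],
    }
    return NetworkFixture(edge_lists=edge_lists, annotation=annotation,
                          term_names=term_names, truth=truth)


def write_network_fixture(fx: NetworkFixture, out_dir: str | Path) -> Path:
    """Write edge-list TSVs, the annotation TSV, and the truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for source, edges in fx.edge_lists.items():
        with open(out / f"{source}.tsv", "w") as fh:
            fh.write("#geneA\tgeneB\n")
            for a, b in edges:
                fh.write(f"{a}\t{b}\n")
    with open(out / "annotation.tsv", "w") as fh:
        fh.write("#gene\tterm_id\tterm_name\n")
        for g in sorted(fx.annotation):
            for t in sorted(fx.annotation[g]):
                fh.write(f"{g}\t{t}\t{fx.term_names.get(t, t)}\n")
    with open(out / "truth.json", "w") as fh:
        json.dump(fx.truth, fh, indent=1, sort_keys=True)
    return out
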