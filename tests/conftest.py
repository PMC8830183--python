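"""Shared fixtures: tiny matrices, a default synthetic cohort, VCF writers."""

from __future__ import annotations

import numpy as np
import pytest

from panelpatterns.synthetic_fixtures import (
    SyntheticCohortSpec,
    simulate_cohort,
    simulate_network_fixture,
)
from panelpatterns.variant_matrix import GenotypeMatrix, VariantKey


def make_matrix(values, mode="binary", chrom="1"):
    """GenotypeMatrix from a dense array with auto-generated identifiers."""
    values = np.asarray(values, dtype=np.int8)
    variants = [VariantKey(chrom, 100 + 10 * i, "A", "G") for i in range(values.shape[0])]
    samples = [f"S{j + 1:02d}" for j in range(values.shape[1])]
    return GenotypeMatrix(variants, samples, values, mode)


VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=1>\n"
    "##contig=<ID=2>\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


def write_vcf(path, records, sample="S1", extra_samples=()):
    """Write a minimal VCF; records are (chrom, pos, id, ref, alt, qual, gt) tuples."""
    cols = "\t".join(["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER",
                      "INFO", "FORMAT", sample, *extra_samples])
    lines = [VCF_HEADER + cols]
    for chrom, pos, vid, ref, alt, qual, *gts in records:
        q = "." if qual is None else f"{qual:g}"
        lines.append(f"{chrom}\t{pos}\t{vid}\t{ref}\t{alt}\t{q}\tPASS\t.\tGT\t"
                     + "\t".join(gts))
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture(scope="session")
def default_cohort():
    return simulate_cohort(SyntheticCohortSpec.default(seed=0))


@pytest.fixture(scope="session")
def network_fixture():
    return simulate_network_fixture(seed=0)
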