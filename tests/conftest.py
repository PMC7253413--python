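"""Shared fixtures: tiny hand-written VCFs and reusable synthetic bundles."""

from __future__ import annotations

import pytest

from mnvkit import CohortSpec, GeneSpec, generate_reference, plant_cohort
from mnvkit.synthetic import RepeatSpec

VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID={contig},length=100000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}
"""


def write_vcf(path, samples, rows, contig="1"):
    """Write a minimal phased VCF.

    ``rows`` are (pos, ref, alt, [per-sample GT:PS:GQ:DP:AD strings]) or
    (pos, ref, alt, fields, filter).
    """
    with open(path, "w") as fh:
        fh.write(VCF_HEADER.format(contig=contig, samples="\t".join(samples)))
        for row in rows:
            pos, ref, alt, fields = row[:4]
            filt = row[4] if len(row) > 4 else "PASS"
            fh.write(
                f"{contig}\t{pos}\t.\t{ref}\t{alt}\t100\t{filt}\t.\t"
                "GT:PS:GQ:DP:AD\t" + "\t".join(fields) + "\n"
            )
    return path


HET = "0|1:{ps}:99:30:15,15"
HET_FLIP = "1|0:{ps}:99:30:15,15"
HOM = "1|1:.:99:30:0,30"
REF = "0|0:.:99:30:30,0"


@pytest.fixture(scope="session")
def tract_bundle():
    """20 kb contig with hetero-dinucleotide tracts and one gene."""
    tracts = [RepeatSpec("TA", 8, 2000 + 300 * i) for i in range(10)]
    tracts += [RepeatSpec("CA", 8, 5200 + 300 * i) for i in range(10)]
    return generate_reference(
        20_000,
        repeat_spec=tracts,
        gene_spec=[GeneSpec("GENE1", 9001, 300, "+")],
        seed=11,
    )


@pytest.fixture(scope="session")
def mixed_cohort(tract_bundle, tmp_path_factory):
    """Small mixed-mechanism cohort with its truth manifest."""
    path = tmp_path_factory.mktemp("cohort") / "mixed.vcf"
    spec = CohortSpec(
        n_samples=40,
        n_events=60,
        mechanism_mix={"independent_snv": 0.5, "pol_zeta": 0.3, "slippage": 0.2},
        trans_pair_rate=0.1,
    )
    manifest = plant_cohort(tract_bundle, spec, path, seed=7)
    return path, manifest
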