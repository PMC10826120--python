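"""Published significant SNP triplets for late-onset Alzheimer disease.

The prioritization workflow this package implements was originally applied
to three controlled-access case-control cohorts (GenADA, ADNI, NCRAD).
The genotypes are not publicly available, but the final reported triplet
tables are; the GenADA and ADNI tables are transcribed here so that the
table-level bookkeeping (unique-SNP counting, the T -> chi-square(1 df)
p-value mapping) can be checked against the published numbers.

Each record is ``(snp1, snp2, snp3, t_ig, p_value, perm_p)`` with the
p-values exactly as printed (truncated to three decimals).
"""

from __future__ import annotations

__all__ = ["GENADA_TRIPLETS", "ADNI_TRIPLETS", "triplet_ids"]

# 8 significant triplets, GenADA cohort (19 unique SNPs)
GENADA_TRIPLETS: list[tuple[str, str, str, float, float, float]] = [
    ("rs17793957", "rs605928", "rs9911460", 8.50, 0.003, 0.001),
    ("rs7045548", "rs1795977", "rs11652714", 8.25, 0.004, 0.001),
    ("rs1879019", "rs17081694", "rs605928", 6.65, 0.009, 0.002),
    ("rs1608169", "rs11862388", "rs16993582", 7.14, 0.007, 0.003),
    ("rs4895529", "rs9314604", "rs17081694", 8.47, 0.003, 0.006),
    ("rs17067596", "rs9314604", "rs17081694", 8.46, 0.003, 0.008),
    ("rs10050568", "rs2978012", "rs6098412", 7.76, 0.005, 0.015),
    ("rs1879019", "rs1519959", "rs136687", 8.48, 0.003, 0.036),
]

# 17 significant triplets, ADNI cohort (26 unique SNPs)
ADNI_TRIPLETS: list[tuple[str, str, str, float, float, float]] = [
    ("rs9366664", "rs3780792", "rs1150360", 8.53, 0.003, 0.001),
    ("rs6705017", "rs10017010", "rs557098", 7.51, 0.006, 0.001),
    ("rs11749731", "rs3780792", "rs7157639", 6.74, 0.009, 0.001),
    ("rs1023276", "rs324389", "rs2824808", 8.81, 0.002, 0.002),
    ("rs6751810", "rs4561856", "rs1023276", 7.92, 0.004, 0.002),
    ("rs4561856", "rs4409091", "rs2633466", 7.61, 0.005, 0.002),
    ("rs4561856", "rs10807701", "rs2824808", 7.55, 0.005, 0.002),
    ("rs7091014", "rs11006011", "rs2633466", 7.47, 0.006, 0.002),
    ("rs6856771", "rs7157639", "rs2824808", 8.18, 0.004, 0.003),
    ("rs9366664", "rs10960174", "rs1150360", 7.69, 0.005, 0.003),
    ("rs11749731", "rs10807701", "rs7157639", 7.42, 0.006, 0.003),
    ("rs6705017", "rs11006011", "rs2633466", 7.77, 0.005, 0.005),
    ("rs9313264", "rs12056012", "rs2633466", 7.69, 0.005, 0.005),
    ("rs6705017", "rs2633466", "rs462074", 7.38, 0.006, 0.006),
    ("rs10017010", "rs9313264", "rs2207851", 8.65, 0.003, 0.008),
    ("rs4561856", "rs9896368", "rs2824808", 8.88, 0.002, 0.009),
    ("rs4561856", "rs7157639", "rs717840", 7.784, 0.005, 0.022),
]


def triplet_ids(table: list[tuple]) -> list[tuple[str, str, str]]:
    """The (snp1, snp2, snp3) id-triples of a reference table."""
    return [(r[0], r[1], r[2]) for r in table]
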