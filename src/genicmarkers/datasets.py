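"""Published worked-example inputs for the blackgram marker study.

Small printed tables from the wild-blackgram (Vigna mungo var. silvestris)
immature-seed transcriptome study, shipped as in-package data so the
pipeline's summarizers can be exercised on the study's own numbers: the
31-marker germplasm panel (allele counts and PIC per genic-SSR locus), the
dataset-level SSR/SNP composition counts, and the expression/assembly
totals.  These are inputs for worked examples — the underlying reads,
band scores and per-locus genotypes were never published.
"""

from __future__ import annotations

# (marker, alleles per locus, PIC) for the 31 genic-SSR markers screened on
# 27 blackgram genotypes.
MARKER_PANEL: list[tuple[str, int, float]] = [
    ("TWSSR-1", 2, 0.28),
    ("TWSSR-4", 2, 0.21),
    ("TWSSR-8", 3, 0.76),
    ("TWSSR-9", 3, 0.62),
    ("TWSSR-10", 5, 0.67),
    ("TWSSR-11", 2, 0.53),
    ("TWSSR-12", 4, 0.49),
    ("TWSSR-13", 2, 0.14),
    ("TWSSR-14", 3, 0.34),
    ("TWSSR-15", 3, 0.60),
    ("TWSSR-16", 4, 0.50),
    ("TWSSR-19", 3, 0.67),
    ("TWSSR-20", 4, 0.72),
    ("TWSSR-24", 1, 0.14),
    ("TWSSR-31", 2, 0.58),
    ("TWSSR-34", 2, 0.59),
    ("TWSSR-47", 3, 0.48),
    ("TWSSR-48", 2, 0.50),
    ("TWSSR-57", 2, 0.48),
    ("TWSSR-59", 3, 0.57),
    ("TWSSR-61", 3, 0.85),
    ("TWSSR-62", 4, 0.69),
    ("TWSSR-66", 3, 0.52),
    ("TWSSR-68", 3, 0.79),
    ("TWSSR-72", 2, 0.46),
    ("TWSSR-74", 4, 0.77),
    ("TWSSR-76", 1, 0.65),
    ("TWSSR-81", 1, 0.36),
    ("TWSSR-82", 3, 0.69),
    ("TWSSR-86", 3, 0.54),
    ("TWSSR-87", 3, 0.46),
]

#: Dataset-level totals from the transcriptome assembly.
N_TRANSCRIPTS = 40178
MEAN_TRANSCRIPT_BP = 446
TOTAL_TRANSCRIPT_BP = N_TRANSCRIPTS * MEAN_TRANSCRIPT_BP

#: SSR counts by unit length (di, tri, plus the remaining unit lengths
#: pooled — the study prints only the di/tri breakdown and the total).
SSR_TOTAL = 1621
SSR_BY_UNIT = {"di": 490, "tri": 646, "other": 1621 - 490 - 646}

#: SSR counts by ORF-relative position (plus unclassified: no ORF found).
SSR_BY_REGION = {"CDS": 977, "UTR": 610, "UNCLASSIFIED": 34}

#: SNP totals and splits.
SNP_TOTAL = 1844
SNP_TS = 1129
SNP_TV = 716
SNP_HET = 17
SNP_HOM = 1828
SNP_BY_REGION = {"CDS": 1291, "UTR": 518, "UNCLASSIFIED": 36}

#: Diversity panel totals as printed.
PANEL_GENOTYPES = 27
PANEL_LOCI = 31
PANEL_ALLELES = 89

#: Differential expression totals between wild (treated) and cultivar (control).
DEG_UP = 1116
DEG_DOWN = 1190

#: Homozygote Tm-difference ranges (degC) per HRM SNP class with the SNP
#: counts assigned to each class in the melt validation.
HRM_CLASS_COUNTS = {"I": 31, "II": 15, "III": 2, "IV": 8}
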