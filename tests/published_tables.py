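"""Published reference values from the rheumatoid-arthritis synovium study
whose analysis this package re-implements, used as worked examples.

``CONSENSUS_ROWS``: the 23 mitochondrial genes differentially expressed in at
least three synovial microarray datasets — per-gene counts of datasets with
up/down-regulation, the published consensus class, and the maximum fold
change (linear scale and the printed log2 value).

``OXPHOS_ROWS``: the 11 respiratory-chain (OxPhos) subunit genes that were
differentially expressed, with their up/down dataset counts.

``SUPPORT_HISTOGRAM``: published counts of network edges whose partners were
co-expressed in exactly 1..5 of the six datasets.

``DEG_DATASET_COUNTS``: published counts of mitochondrial DEGs by the number
of datasets in which they were differentially expressed (6, 5, 4, 3, 2).
"""

# gene, n_up, n_down, total, consensus class, max FC (linear), printed log2
CONSENSUS_ROWS = [
    ("AK4", 1, 2, 3, "Mixed", 1.87, 0.90),
    ("AKR1B10", 0, 3, 3, "Down", 0.26, -1.94),
    ("BCL2", 3, 1, 4, "Mixed", 0.38, -1.39),
    ("C10orf10", 1, 2, 3, "Mixed", 0.17, -2.55),
    ("DNAJC15", 3, 0, 3, "Up", 1.72, 0.78),
    ("IDH2", 3, 0, 3, "Up", 3.66, 1.87),
    ("MAOA", 0, 3, 3, "Down", 0.09, -3.47),
    ("MCCC1", 0, 3, 3, "Down", 0.58, -0.78),
    ("PDK4", 0, 3, 3, "Down", 0.12, -3.05),
    ("YME1L1", 3, 0, 3, "Up", 3.22, 1.68),
    ("PRDX4", 3, 0, 3, "Up", 4.62, 2.20),
    ("UCP2", 4, 0, 4, "Up", 7.94, 2.98),
    ("C10orf2", 0, 3, 3, "Down", 0.61, -0.71),
    ("ACOT7", 5, 0, 5, "Up", 2.75, 1.45),
    ("EFHD1", 0, 3, 3, "Down", 0.26, -1.94),
    ("IFI27", 4, 0, 4, "Up", 3.54, 1.82),
    ("KMO", 5, 0, 5, "Up", 4.55, 2.18),
    ("PLGRKT", 3, 0, 3, "Up", 2.59, 1.37),
    ("SLC16A7", 2, 4, 6, "Mixed", 0.28, -1.83),
    ("CASP8", 3, 0, 3, "Up", 2.40, 1.26),
    ("LAP3", 5, 0, 5, "Up", 2.73, 1.44),
    ("PDK1", 4, 0, 4, "Up", 4.81, 2.26),
    ("C15orf48", 3, 0, 3, "Up", 30.45, 4.92),
]

# gene, n datasets up, n datasets down, respiratory-chain complex
OXPHOS_ROWS = [
    ("NDUFB4", 0, 1, "I"),
    ("NDUFB6", 0, 1, "I"),
    ("NDUFB7", 1, 0, "I"),
    ("NDUFB9", 0, 1, "I"),
    ("NDUFS4", 0, 1, "I"),
    ("UQCRFS1", 0, 1, "III"),
    ("UQCR11", 1, 0, "III"),
    ("COX6A1", 1, 1, "IV"),
    ("COX7A1", 0, 2, "IV"),
    ("ATP5E", 2, 0, "V"),
    ("ATP5G3", 0, 1, "V"),
]

# support level (datasets with co-expressed partners) -> published edge count
SUPPORT_HISTOGRAM = {5: 13, 4: 65, 3: 184, 2: 618, 1: 1828}

# number of datasets a DEG appeared in -> published gene count
DEG_DATASET_COUNTS = {6: 1, 5: 3, 4: 4, 3: 15, 2: 60}
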