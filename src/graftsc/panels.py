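"""Default gene catalogs: lineage marker panels, sex panel, blacklist seeds,
matrisome and immunoglobulin gene sets.

These are small editable defaults; every public function accepts a
user-supplied catalog in their place. Gene identity is by HGNC symbol
throughout.
"""

from __future__ import annotations

# Kidney lineage marker panels (cell type -> marker symbols). Used both to
# annotate clusters and, by the simulator, to plant cell-type structure.
DEFAULT_MARKER_PANELS: dict[str, list[str]] = {
    "PT": ["MIOX", "ANPEP", "SLC13A1", "LRP2", "CUBN"],
    "PG": ["PROM1", "CD24", "VIM", "CDH2", "HAVCR1"],
    "LH": ["UMOD", "SLC12A1", "CLDN16"],
    "CD": ["AQP2", "AQP3", "GATA3"],
    "IC-A": ["ATP6V0D2", "SLC4A1", "ATP6V1G3"],
    "FB": ["DCN", "COL1A1", "LUM", "PDGFRA", "MFAP5"],
    "EC": ["PECAM1", "CDH5", "PLVAP", "EMCN"],
    "PC.vSMC": ["RGS5", "PDGFRB", "ACTA2", "NOTCH3"],
    "TC": ["CD3D", "CD3E", "TRAC", "IL7R"],
    "NK": ["NKG7", "GNLY", "KLRD1"],
    "MAC": ["CD68", "CD163", "MS4A4A", "STAB1"],
    "MONO": ["FCN1", "S100A8", "VCAN"],
    "BC.PLASMA": ["CD79A", "MZB1", "JCHAIN", "MS4A1"],
}

# Broad lineage panels for the two-lineage doublet screen. Disjoint by
# construction (validated at use).
DEFAULT_LINEAGE_PANELS: dict[str, list[str]] = {
    "epithelial": ["MIOX", "ANPEP", "LRP2", "UMOD", "AQP2", "PROM1"],
    "endothelial": ["PECAM1", "CDH5", "PLVAP", "EMCN"],
    "stromal": ["DCN", "COL1A1", "LUM", "RGS5", "ACTA2"],
    "immune": ["CD3D", "CD3E", "CD68", "CD163", "CD79A", "MZB1"],
}

# Sex-linked origin markers: XIST (inactive-X lncRNA, female-specific) and
# Y-chromosome genes escaping the pseudoautosomal region (male-specific).
FEMALE_GENES = ["XIST"]
MALE_GENES = ["RPS4Y1", "EIF1AY", "DDX3Y"]
# RPS4Y is an older alias of RPS4Y1; both spellings occur in the literature.
GENE_ALIASES = {"RPS4Y": "RPS4Y1"}

# The 13 protein-coding mitochondrial genes (MT- prefix drives QC).
MT_GENES = [
    "MT-ND1", "MT-ND2", "MT-CO1", "MT-CO2", "MT-ATP8", "MT-ATP6",
    "MT-CO3", "MT-ND3", "MT-ND4L", "MT-ND4", "MT-ND5", "MT-ND6", "MT-CYB",
]

# Blacklist defaults: ubiquitous ribosomal proteins, MALAT1, and small-RNA
# symbol classes removed before clustering.
BLACKLIST_PREFIXES = ["RPS", "RPL"]
BLACKLIST_EXACT = ["MALAT1"]
BLACKLIST_CLASS_PREFIXES = ["MIR", "SNORD", "SNORA", "SNORB", "SCARNA"]

# Immunoglobulin constant-region genes grouped by heavy/light chain class.
IG_HEAVY_CLASSES: dict[str, list[str]] = {
    "IGHG": ["IGHG1", "IGHG2", "IGHG3", "IGHG4"],
    "IGHA": ["IGHA1", "IGHA2"],
    "IGHM": ["IGHM"],
    "IGHD": ["IGHD"],
    "IGHE": ["IGHE"],
}
IG_LIGHT_CLASSES: dict[str, list[str]] = {
    "IGK": ["IGKC"],
    "IGL": ["IGLC1", "IGLC2", "IGLC3", "IGLC7"],
    "IGLL5": ["IGLL5"],
}
IG_HEAVY_ORDER = ["IGHG", "IGHA", "IGHM", "IGHD", "IGHE"]
IG_LIGHT_ORDER = ["IGK", "IGL", "IGLL5"]

# Seed matrisome catalog (category -> representative genes). Editable TSV
# export/import lives in graftsc.io; categories are disjoint.
DEFAULT_MATRISOME: dict[str, list[str]] = {
    "collagens": [
        "COL1A1", "COL1A2", "COL3A1", "COL4A1", "COL4A2", "COL5A1",
        "COL6A1", "COL6A2", "COL6A3", "COL18A1",
    ],
    "proteoglycans": [
        "DCN", "BGN", "LUM", "VCAN", "HSPG2", "PRELP",
    ],
    "secreted factors": [
        "CCL2", "CXCL1", "CXCL6", "CXCL9", "CXCL10", "CXCL11",
        "S100A4", "S100A8", "S100A9", "S100A10", "SFRP2", "SFRP4",
    ],
}

PARENCHYMAL_TYPES = {"PT", "PT1", "PT2", "PG", "PG1", "PG2", "LH", "CD",
                     "IC-A", "LH.CD.IC", "EC", "PC.vSMC"}
IMMUNE_TYPES = {"TC", "NK", "MAC", "MONO", "MAC.DC", "BC.PLASMA", "DC",
                "BC", "PLASMA", "MAST", "CTC"}
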