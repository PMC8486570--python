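"""Default ddPCR assay panel, control assays, class labels and class merging.

The panel here is a *synthetic* reconstruction of an 89-assay custom ddPCR
miRNA plate: it contains every assay named in the workflow it emulates
(miR-122-5p and miR-21-5p, the candidate reference / added assays, the
prognostic miRNAs) padded with real human miRNA identifiers to 89 entries.
Analyses never depend on which padding miRNAs were chosen, only on the panel
size and on the named special assays.
"""

from __future__ import annotations

# miRNA assays explicitly part of the emulated panel.
_NAMED_ASSAYS = [
    # excluded from prediction downstream (liver microenvironment / non-specific)
    "miR-122-5p",
    "miR-21-5p",
    # prognostic screen hits
    "miR-124-3p",
    "miR-9-3p",
    "miR-149-5p",
    "miR-372-3p",
    "miR-485-5p",
    "miR-375",
    "miR-25-3p",
    "miR-27b-3p",
    "miR-181a-2-3p",
    "miR-10b-5p",
    "miR-96-5p",
    "miR-423-5p",
    "miR-214-3p",
    # candidate reference / panel-widening additions
    "miR-661",
    "miR-649",
    "miR-24-3p",
    "miR-16-5p",
    "miR-320a",
    "miR-224-5p",
    "miR-331-3p",
    "miR-103a-3p",
]

# Real human miRNA identifiers used to pad the synthetic panel to 89 assays.
_PADDING_ASSAYS = [
    "let-7a-5p", "let-7b-5p", "let-7c-5p",
    "miR-1-3p", "miR-7-5p", "miR-10a-5p", "miR-15a-5p", "miR-17-5p",
    "miR-18a-5p", "miR-19b-3p", "miR-20a-5p", "miR-22-3p", "miR-23a-3p",
    "miR-26a-5p", "miR-29a-3p", "miR-30a-5p", "miR-31-5p", "miR-34a-5p",
    "miR-92a-3p", "miR-99a-5p", "miR-100-5p", "miR-101-3p", "miR-106b-5p",
    "miR-125b-5p", "miR-126-3p", "miR-127-3p", "miR-128-3p", "miR-130a-3p",
    "miR-133a-3p", "miR-135b-5p", "miR-138-5p", "miR-141-3p", "miR-143-3p",
    "miR-145-5p", "miR-146a-5p", "miR-148a-3p", "miR-150-5p", "miR-152-3p",
    "miR-155-5p", "miR-182-5p", "miR-183-5p", "miR-187-3p", "miR-192-5p",
    "miR-194-5p", "miR-195-5p", "miR-196a-5p", "miR-199a-5p", "miR-200a-3p",
    "miR-200b-3p", "miR-200c-3p", "miR-203a-3p", "miR-204-5p", "miR-205-5p",
    "miR-210-3p", "miR-215-5p", "miR-217-5p", "miR-218-5p", "miR-221-3p",
    "miR-222-3p", "miR-223-3p", "miR-296-5p", "miR-338-3p", "miR-342-3p",
    "miR-345-5p", "miR-365a-3p", "miR-429",
]

#: The 89 miRNA assays quantified per sample (copies per microlitre).
DEFAULT_PANEL: tuple[str, ...] = tuple(_NAMED_ASSAYS + _PADDING_ASSAYS)

#: Control assays on the plate; never part of normalization or prediction.
CONTROL_ASSAYS: tuple[str, ...] = ("SNORD44", "SNORD48", "snRNAU6", "UniSp3", "UniSp6")

#: Assays dropped before classifier training/prediction: miR-122-5p is inflated
#: by the liver microenvironment in liver-site biopsies and miR-21-5p is
#: ubiquitously expressed in solid tumors (non-specific).
DEFAULT_EXCLUSIONS: tuple[str, ...] = ("miR-122-5p", "miR-21-5p")

#: The 19 histological classes of the reference cohort.
HISTOLOGICAL_CLASSES: tuple[str, ...] = (
    "BLCA", "CHOL", "CRC", "GI-NET", "HNSC", "KIRC", "KIRP", "LBC", "LIHC",
    "LUAD", "LUSC", "OV", "PAAD", "PRAD", "SKCM", "STAD", "TGSC", "TNBC",
    "UCEC",
)

#: Merge map: gastric + colorectal adenocarcinoma share miRNA patterns and are
#: predicted as one class (STAD-CRC); renal clear-cell and papillary likewise
#: merge to KICA. 19 histological labels -> 17 prediction classes.
DEFAULT_CLASS_MAP: dict[str, str] = {
    **{c: c for c in HISTOLOGICAL_CLASSES},
    "STAD": "STAD-CRC",
    "CRC": "STAD-CRC",
    "KIRC": "KICA",
    "KIRP": "KICA",
    # identity on the merged labels makes the map idempotent
    "STAD-CRC": "STAD-CRC",
    "KICA": "KICA",
}

#: The 17 prediction classes (image of DEFAULT_CLASS_MAP).
PREDICTION_CLASSES: tuple[str, ...] = tuple(sorted(set(DEFAULT_CLASS_MAP.values())))

#: Sex-incompatible prediction classes, zeroed by the sex filter.
MALE_ONLY_CLASSES: frozenset[str] = frozenset({"TGSC", "PRAD"})
FEMALE_ONLY_CLASSES: frozenset[str] = frozenset({"OV", "UCEC"})

#: Biopsy-site vocabulary for simulated metastases (sites seen in CUP cohorts).
KNOWN_BIOPSY_SITES: tuple[str, ...] = (
    "bone", "bone marrow", "brain", "breast", "cerebellum", "colon", "dermis",
    "duodenum", "kidney", "liver", "lung", "lymph node", "muscle",
    "pericardium", "pleura", "prostate", "seminal vesicle", "skin",
    "soft tissue", "stomach", "thyroid",
)

assert len(DEFAULT_PANEL) == 89, len(DEFAULT_PANEL)
assert len(set(DEFAULT_PANEL)) == 89
assert len(PREDICTION_CLASSES) == 17
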