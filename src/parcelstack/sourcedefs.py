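"""Feature-source vocabulary shared by extraction and modelling.

A *source* is one (feature type, parcellation) pair. Six feature types
are extracted per parcellation: three regional (ALFF, fALFF, ReHo) and
three connectivity (full correlation, partial correlation, sparse
precision). With the canonical 14-parcellation registry this yields the
84 sources of the full ensemble.
"""

REGIONAL_FEATURE_TYPES = ("alff", "falff", "reho")
CONNECTIVITY_FEATURE_TYPES = ("corr", "pcorr", "prec")
FEATURE_TYPES = REGIONAL_FEATURE_TYPES + CONNECTIVITY_FEATURE_TYPES

FEATURE_TYPE_LABELS = {
    "alff": "ALFF",
    "falff": "fALFF",
    "reho": "ReHo",
    "corr": "FC-correlation",
    "pcorr": "FC-partial-correlation",
    "prec": "FC-precision",
}

#: sizes (n_rois) of the 14 canonical published parcellations, in the
#: conventional registry order; regional feature count equals n_rois and
#: connectivity feature count equals n_rois*(n_rois-1)/2
CANONICAL_PARCELLATION_SIZES = {
    "yeo": 17,
    "smith20": 20,
    "harvard_sub_25": 22,
    "msdl": 39,
    "smith70": 70,
    "harvard_cort_25": 96,
    "aal": 116,
    "basc_multiscale_122": 122,
    "destrieux": 148,
    "dosenbach": 160,
    "basc_multiscale_197": 197,
    "power": 264,
    "basc_multiscale_325": 325,
    "basc_multiscale_444": 444,
}
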