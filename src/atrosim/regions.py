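"""Region-label vocabulary and the five-scheme heterogeneity hierarchy.

The fully heterogeneous model distinguishes 17 anatomical regions; four
coarser schemes (9R, 4R, 2R, 1R) merge them into progressively more
homogeneous groups.  The cerebrospinal-fluid shell (CSF) and the
ventricular cavities (VENTRICLE) are material labels of their own and are
never merged into anatomical groups.
"""

from __future__ import annotations

# 17 anatomical labels (abbreviation -> full name)
ANATOMICAL_LABELS: dict[str, str] = {
    "FC": "frontal cortex",
    "MC": "motor cortex",
    "VC": "visual cortex",
    "CI": "insular cortex",
    "TL": "temporal lobe",
    "CR": "corona radiata",
    "NC": "nucleus caudatus",
    "Pa": "pallidum",
    "Pu": "putamen",
    "Me": "medulla",
    "P": "pons",
    "M": "midbrain",
    "Th": "thalamus",
    "CB": "cerebellum",
    "Am": "amygdala",
    "Hi": "hippocampus",
    "CC": "corpus callosum",
}

CSF = "CSF"
VENTRICLE = "VENTRICLE"
NON_ANATOMICAL = (CSF, VENTRICLE)

CORTICAL_LABELS = ("FC", "MC", "VC", "CI", "TL")
BRAINSTEM_LABELS = ("M", "P", "Me")  # midbrain, pons, medulla (superior->inferior)

ALL_LABELS = tuple(ANATOMICAL_LABELS) + NON_ANATOMICAL

SCHEMES = ("17R", "9R", "4R", "2R", "1R")

# 17R -> 9R grouping
_MAP_9R = {
    "FC": "Cortex", "MC": "Cortex", "VC": "Cortex", "CI": "Cortex", "TL": "Cortex",
    "CR": "Corona radiata",
    "NC": "Basal ganglia", "Pa": "Basal ganglia", "Pu": "Basal ganglia",
    "Me": "Brain stem", "P": "Brain stem",
    "M": "Midbrain", "Th": "Midbrain",
    "CB": "Cerebellum",
    "Am": "Amygdala",
    "Hi": "Hippocampus",
    "CC": "Corpus callosum",
}

# 9R -> 4R grouping
_MAP_9R_TO_4R = {
    "Cortex": "Cortex",
    "Corona radiata": "Corona radiata",
    "Basal ganglia": "Internal brain structures",
    "Brain stem": "Internal brain structures",
    "Midbrain": "Internal brain structures",
    "Cerebellum": "Internal brain structures",
    "Amygdala": "Internal brain structures",
    "Hippocampus": "Internal brain structures",
    "Corpus callosum": "Corpus callosum",
}

# 4R -> 2R grouping
_MAP_4R_TO_2R = {
    "Cortex": "Cortex",
    "Corona radiata": "Subcortical region",
    "Internal brain structures": "Subcortical region",
    "Corpus callosum": "Subcortical region",
}

_MAP_2R_TO_1R = {"Cortex": "Homogeneous", "Subcortical region": "Homogeneous"}


def _compose(outer: dict[str, str], inner: dict[str, str]) -> dict[str, str]:
    return {k: outer[v] for k, v in inner.items()}


def scheme_map(scheme: str) -> dict[str, str]:
    """Mapping 17R anatomical label -> group label of *scheme*.

    CSF and VENTRICLE always map to themselves and are included in the
    returned mapping for convenience.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown region scheme {scheme!r}; expected one of {SCHEMES}")
    if scheme == "17R":
        m = {k: k for k in ANATOMICAL_LABELS}
    elif scheme == "9R":
        m = dict(_MAP_9R)
    elif scheme == "4R":
        m = _compose(_MAP_9R_TO_4R, _MAP_9R)
    elif scheme == "2R":
        m = _compose(_MAP_4R_TO_2R, _compose(_MAP_9R_TO_4R, _MAP_9R))
    else:  # 1R
        m = {k: "Homogeneous" for k in ANATOMICAL_LABELS}
    m[CSF] = CSF
    m[VENTRICLE] = VENTRICLE
    return m


def step_map(fine: str, coarse: str) -> dict[str, str]:
    """Mapping from the groups of scheme *fine* to the groups of *coarse*.

    Valid only for the nested hierarchy 17R -> 9R -> 4R -> 2R -> 1R.
    """
    order = {s: i for i, s in enumerate(SCHEMES)}
    if fine not in order or coarse not in order:
        raise ValueError(f"unknown scheme in ({fine!r}, {coarse!r})")
    if order[coarse] < order[fine]:
        raise ValueError(f"{coarse} is finer than {fine}; merges only coarsen")
    fine_map = scheme_map(fine)
    coarse_map = scheme_map(coarse)
    out: dict[str, str] = {}
    for lab in ALL_LABELS:
        g_f, g_c = fine_map[lab], coarse_map[lab]
        if out.setdefault(g_f, g_c) != g_c:
            raise RuntimeError("scheme hierarchy is not nested")  # pragma: no cover
    return out


def scheme_groups(scheme: str) -> dict[str, tuple[str, ...]]:
    """Group label -> tuple of constituent 17R labels (anatomical only)."""
    m = scheme_map(scheme)
    groups: dict[str, list[str]] = {}
    for lab in ANATOMICAL_LABELS:
        groups.setdefault(m[lab], []).append(lab)
    return {g: tuple(v) for g, v in groups.items()}
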