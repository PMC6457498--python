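"""Canonical white-matter tract labels.

The 48-region JHU ICBM-DTI-81 white-matter parcellation is the region set
used throughout the pipeline: integer atlas labels 1..48 map onto the tract
names below (0 is background).
"""

from __future__ import annotations

JHU_TRACTS: tuple[str, ...] = (
    "Middle cerebellar peduncle",
    "Pontine crossing tract",
    "Genu of corpus callosum",
    "Body of corpus callosum",
    "Splenium of corpus callosum",
    "Fornix column and body",
    "Corticospinal tract R",
    "Corticospinal tract L",
    "Medial lemniscus R",
    "Medial lemniscus L",
    "Inferior cerebellar peduncle R",
    "Inferior cerebellar peduncle L",
    "Superior cerebellar peduncle R",
    "Superior cerebellar peduncle L",
    "Cerebral peduncle R",
    "Cerebral peduncle L",
    "Anterior limb of internal capsule R",
    "Anterior limb of internal capsule L",
    "Posterior limb of internal capsule R",
    "Posterior limb of internal capsule L",
    "Retrolenticular part of internal capsule R",
    "Retrolenticular part of internal capsule L",
    "Anterior corona radiata R",
    "Anterior corona radiata L",
    "Superior corona radiata R",
    "Superior corona radiata L",
    "Posterior corona radiata R",
    "Posterior corona radiata L",
    "Posterior thalamic radiation R",
    "Posterior thalamic radiation L",
    "Sagittal stratum R",
    "Sagittal stratum L",
    "External capsule R",
    "External capsule L",
    "Cingulum cingulate gyrus R",
    "Cingulum cingulate gyrus L",
    "Cingulum hippocampus R",
    "Cingulum hippocampus L",
    "Fornix stria terminalis R",
    "Fornix stria terminalis L",
    "Superior longitudinal fasciculus R",
    "Superior longitudinal fasciculus L",
    "Superior fronto-occipital fasciculus R",
    "Superior fronto-occipital fasciculus L",
    "Uncinate fasciculus R",
    "Uncinate fasciculus L",
    "Tapetum R",
    "Tapetum L",
)

N_TRACTS = len(JHU_TRACTS)

#: label (1-based) -> tract name
LABEL_TO_NAME: dict[int, str] = {i + 1: name for i, name in enumerate(JHU_TRACTS)}
NAME_TO_LABEL: dict[str, int] = {name: i + 1 for i, name in enumerate(JHU_TRACTS)}

#: Tracts classified into the most-injured group in the reference locked-in
#: syndrome cohort (posterior membership probability > 0.5).
DEFAULT_GROUP2_TRACTS: tuple[str, ...] = (
    "Medial lemniscus R",
    "Medial lemniscus L",
    "Superior fronto-occipital fasciculus R",
    "Superior cerebellar peduncle L",
)

#: Tracts whose group-2 assignment is anatomically suspect: ventricular
#: atrophy can misalign the superior fronto-occipital fasciculus ROIs during
#: registration, inflating their apparent injury.
ARTEFACT_SUSPECT_TRACTS: tuple[str, ...] = (
    "Superior fronto-occipital fasciculus R",
    "Superior fronto-occipital fasciculus L",
)

METRICS: tuple[str, ...] = ("FA", "MD", "AD", "RD")
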