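"""Desikan–Killiany cortical parcellation groupings.

ROIs are grouped into the four primary cortical lobes (frontal, parietal,
temporal, occipital; cingulate subregions are assigned to their adjacent
lobes, the insula to none) plus a synthetic "AD-signature" composite of the
regions most vulnerable to AD-related cortical thinning.  The atlas has no
exact "angular gyrus" or "middle frontal gyrus" labels; the signature maps
those onto inferior parietal and rostral+caudal middle frontal, editable via
config.

Seven ROIs are excluded from every analysis by default: four with
subcutaneous-fat-driven exchange-rate artifacts (rostral anterior cingulate,
precentral, postcentral, superior parietal) and three with bSSFP-like
banding above the frontal sinus (medial/lateral orbitofrontal, temporal
pole).  Excluded ROIs are dropped from all lobes, including the AD
signature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

FRONTAL = (
    "superiorfrontal", "rostralmiddlefrontal", "caudalmiddlefrontal",
    "parsopercularis", "parstriangularis", "parsorbitalis",
    "lateralorbitofrontal", "medialorbitofrontal", "precentral",
    "paracentral", "frontalpole", "rostralanteriorcingulate",
    "caudalanteriorcingulate",
)
PARIETAL = (
    "superiorparietal", "inferiorparietal", "supramarginal", "postcentral",
    "precuneus", "posteriorcingulate", "isthmuscingulate",
)
TEMPORAL = (
    "superiortemporal", "middletemporal", "inferiortemporal", "bankssts",
    "fusiform", "transversetemporal", "entorhinal", "temporalpole",
    "parahippocampal",
)
OCCIPITAL = ("lateraloccipital", "lingual", "cuneus", "pericalcarine")

AD_SIGNATURE = (
    "entorhinal", "temporalpole", "inferiortemporal", "inferiorparietal",
    "supramarginal", "superiorparietal", "precuneus",
    "rostralmiddlefrontal", "caudalmiddlefrontal", "superiorfrontal",
)

DEFAULT_EXCLUSIONS = (
    # Rx artifacts (subcutaneous fat)
    "rostralanteriorcingulate", "precentral", "postcentral", "superiorparietal",
    # banding artifacts above the frontal sinus
    "medialorbitofrontal", "lateralorbitofrontal", "temporalpole",
)

SUBCORTICAL_ROIS = ("hippocampus", "amygdala", "thalamus", "caudate",
                    "putamen", "pallidum")
#: subcortical family for Bonferroni correction: six structures + global WM
SUBCORTICAL_FAMILY_SIZE = 7
#: lobar family: four lobes + AD-signature composite
LOBAR_FAMILY_SIZE = 5


@dataclass(frozen=True)
class LobeMap:
    """Mapping atlas ROI -> lobe, with an exclusion list.

    The AD-signature composite may overlap the four lobes; exclusions are
    removed from every lobe before aggregation.
    """

    lobes: dict = field(default_factory=lambda: {
        "frontal": FRONTAL, "parietal": PARIETAL, "temporal": TEMPORAL,
        "occipital": OCCIPITAL, "AD_signature": AD_SIGNATURE})
    exclusions: tuple = DEFAULT_EXCLUSIONS

    def members(self, lobe: str) -> tuple:
        """Non-excluded constituent ROIs of a lobe."""
        try:
            rois = self.lobes[lobe]
        except KeyError:
            raise KeyError(f"unknown lobe {lobe!r}; have {sorted(self.lobes)}") from None
        out = tuple(r for r in rois if r not in self.exclusions)
        if not out:
            raise ValueError(f"lobe {lobe!r} is empty after exclusions")
        return out

    @property
    def lobe_names(self) -> tuple:
        return tuple(self.lobes)
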