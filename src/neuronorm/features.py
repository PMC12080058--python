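"""Feature-name registries for the three modality blocks and the network parcellation.

The T1 block holds 66 cortical grey-matter volumes (Desikan-Killiany, 33
regions per hemisphere) plus 16 subcortical volumes.  The DTI blocks hold
fractional anisotropy (FA) and mean diffusivity (MD) for 32 white-matter
tracts (JHU-style labels).  Cortical regions map onto the seven Yeo
functional networks; subcortical grey matter maps onto medial temporal
lobe, Thalamus or Basal Ganglia.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import pandas as pd

# Desikan-Killiany cortical labels (33 per hemisphere)
_DK_CORTICAL = [
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "frontalpole", "fusiform", "inferiorparietal",
    "inferiortemporal", "insula", "isthmuscingulate", "lateraloccipital",
    "lateralorbitofrontal", "lingual", "medialorbitofrontal",
    "middletemporal", "paracentral", "parahippocampal", "parsopercularis",
    "parsorbitalis", "parstriangularis", "pericalcarine", "postcentral",
    "posteriorcingulate", "precentral", "precuneus",
    "rostralanteriorcingulate", "rostralmiddlefrontal", "superiorfrontal",
    "superiorparietal", "superiortemporal", "supramarginal",
    "transversetemporal",
]

_SUBCORTICAL = [
    "Thalamus", "Caudate", "Putamen", "Pallidum",
    "Hippocampus", "Amygdala", "Accumbens", "VentralDC",
]

# JHU-style white-matter tract labels: 15 bilateral pairs + fornix + genu CC
_TRACTS_BILATERAL = [
    "ATR", "CST", "CGC", "CGH", "IFO", "ILF", "SLF", "UNC", "FX/ST",
    "PTR", "ACR", "SCR", "PCR", "EC", "SS",
]
_TRACTS_MIDLINE = ["FX", "GCC"]


def cortical_features() -> list[str]:
    return [f"{h}_{r}" for h in ("lh", "rh") for r in _DK_CORTICAL]


def subcortical_features() -> list[str]:
    return [f"{h}-{r}" for h in ("Left", "Right") for r in _SUBCORTICAL]


def t1_features() -> list[str]:
    """66 cortical + 16 subcortical grey-matter volume features."""
    return cortical_features() + subcortical_features()


def tract_names() -> list[str]:
    return [f"{t}-{h}" for t in _TRACTS_BILATERAL for h in ("L", "R")] + _TRACTS_MIDLINE


def fa_features() -> list[str]:
    return [f"{t}_FA" for t in tract_names()]


def md_features() -> list[str]:
    return [f"{t}_MD" for t in tract_names()]


@dataclass(frozen=True)
class ModalitySpec:
    """A modality block: name, ordered feature list and outlier tail.

    ``outlier_tail`` encodes the expected direction of disease-related
    change: grey-matter volume and FA decrease ("lower"), MD increases
    ("upper").
    """

    name: Literal["T1", "FA", "MD"]
    features: tuple[str, ...]
    outlier_tail: Literal["lower", "upper"]

    def __post_init__(self) -> None:
        expected = {"T1": "lower", "FA": "lower", "MD": "upper"}
        if self.name in expected and self.outlier_tail != expected[self.name]:
            raise ValueError(
                f"modality {self.name} must use {expected[self.name]!r} tail"
            )


def default_modality_specs() -> list[ModalitySpec]:
    return [
        ModalitySpec("T1", tuple(t1_features()), "lower"),
        ModalitySpec("FA", tuple(fa_features()), "lower"),
        ModalitySpec("MD", tuple(md_features()), "upper"),
    ]


def all_features() -> list[str]:
    out: list[str] = []
    for spec in default_modality_specs():
        out.extend(spec.features)
    return out


# --- network parcellation ------------------------------------------------

YEO_NETWORKS = (
    "Visual", "Somatomotor", "DorsalAttention", "SalienceVentralAttention",
    "Limbic", "Frontoparietal", "DefaultMode",
)
SUBCORTICAL_NETWORKS = ("MedialTemporalLobe", "Thalamus", "BasalGanglia")

# Coarse Desikan-Killiany -> Yeo-7 assignment (majority-overlap style).
_DK_TO_YEO = {
    "cuneus": "Visual", "lateraloccipital": "Visual", "lingual": "Visual",
    "pericalcarine": "Visual",
    "postcentral": "Somatomotor", "precentral": "Somatomotor",
    "paracentral": "Somatomotor", "transversetemporal": "Somatomotor",
    "superiorparietal": "DorsalAttention", "supramarginal": "DorsalAttention",
    "caudalanteriorcingulate": "SalienceVentralAttention",
    "insula": "SalienceVentralAttention",
    "caudalmiddlefrontal": "SalienceVentralAttention",
    "entorhinal": "Limbic", "parahippocampal": "Limbic",
    "lateralorbitofrontal": "Limbic", "medialorbitofrontal": "Limbic",
    "frontalpole": "Limbic",
    "rostralmiddlefrontal": "Frontoparietal",
    "parsopercularis": "Frontoparietal", "parsorbitalis": "Frontoparietal",
    "parstriangularis": "Frontoparietal",
    "bankssts": "DefaultMode", "fusiform": "DefaultMode",
    "inferiorparietal": "DefaultMode", "inferiortemporal": "DefaultMode",
    "isthmuscingulate": "DefaultMode", "middletemporal": "DefaultMode",
    "posteriorcingulate": "DefaultMode", "precuneus": "DefaultMode",
    "rostralanteriorcingulate": "DefaultMode",
    "superiorfrontal": "DefaultMode", "superiortemporal": "DefaultMode",
}

_SUBCORT_TO_NET = {
    "Hippocampus": "MedialTemporalLobe", "Amygdala": "MedialTemporalLobe",
    "Thalamus": "Thalamus",
    "Accumbens": "BasalGanglia", "Pallidum": "BasalGanglia",
    "Putamen": "BasalGanglia", "Caudate": "BasalGanglia",
    # VentralDC has no canonical network assignment; excluded from maps.
}


@dataclass
class NetworkParcellation:
    """Mapping from grey-matter feature name to network label."""

    mapping: dict[str, str] = field(default_factory=dict)

    @property
    def networks(self) -> list[str]:
        seen: list[str] = []
        for v in self.mapping.values():
            if v not in seen:
                seen.append(v)
        return seen

    def network_features(self, network: str) -> list[str]:
        return [f for f, n in self.mapping.items() if n == network]

    @classmethod
    def default(cls) -> "NetworkParcellation":
        mapping: dict[str, str] = {}
        for h in ("lh", "rh"):
            for r in _DK_CORTICAL:
                mapping[f"{h}_{r}"] = _DK_TO_YEO[r]
        for h in ("Left", "Right"):
            for r in _SUBCORTICAL:
                if r in _SUBCORT_TO_NET:
                    mapping[f"{h}-{r}"] = _SUBCORT_TO_NET[r]
        return cls(mapping)

    @classmethod
    def from_file(cls, path: str | Path) -> "NetworkParcellation":
        df = pd.read_csv(path, sep="\t", header=0)
        if df.shape[1] < 2:
            raise ValueError("parcellation file needs two columns: feature, network")
        return cls(dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str))))

    def to_file(self, path: str | Path) -> None:
        pd.DataFrame(
            {"feature": list(self.mapping), "network": list(self.mapping.values())}
        ).to_csv(path, sep="\t", index=False)
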