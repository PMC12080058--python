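"""Directional outlier flagging, outlier-proportion maps, network-level
aggregation and group-wise permutation testing with FDR control.

A region is an outlier for a subject when its deviation z-score crosses
the directional 2.5% threshold: d_uf < -1.96 for volume (T1) and FA
features, d_uf > +1.96 for MD features (strict inequality).  Network
rates count each subject at most once per network — the fraction of
subjects with at least one flagged region in that network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .features import ModalitySpec, NetworkParcellation

__all__ = [
    "OUTLIER_Z",
    "OutlierMap",
    "flag_outliers",
    "outlier_proportions",
    "network_outlier_rate",
    "permutation_test",
    "fdr_correct",
]

OUTLIER_Z = 1.96


@dataclass
class OutlierMap:
    """Per-feature outlier proportions within one stratum."""

    stratum: str
    proportions: pd.Series   # feature -> fraction in [0, 1]
    n: int

    def __post_init__(self):
        if self.n <= 0:
            raise ValueError("stratum must be non-empty")
        if ((self.proportions < 0) | (self.proportions > 1)).any():
            raise ValueError("proportions must lie in [0, 1]")

    def displayed(self, floor: float = 0.025) -> pd.Series:
        """Presentation helper: proportions below the display floor are
        masked (NaN), mirroring grey regions in heat-tables.  Never used
        in statistics."""
        out = self.proportions.copy()
        out[out < floor] = np.nan
        return out


def flag_outliers(duf: pd.DataFrame, specs: list[ModalitySpec]) -> pd.DataFrame:
    """Boolean per-subject x per-feature outlier flags.

    Lower-tail features are flagged iff d_uf < -1.96; upper-tail iff
    d_uf > +1.96.  A value exactly at the threshold is not an outlier.
    Every d_uf column must be covered by exactly one modality spec.
    """
    tails: dict[str, str] = {}
    for spec in specs:
        for f in spec.features:
            tails[f] = spec.outlier_tail
    unknown = [c for c in duf.columns if c not in tails]
    if unknown:
        raise ValueError(f"features without a modality spec: {unknown[:5]}")
    flags = pd.DataFrame(False, index=duf.index, columns=duf.columns)
    for col in duf.columns:
        if tails[col] == "lower":
            flags[col] = duf[col] < -OUTLIER_Z
        else:
            flags[col] = duf[col] > OUTLIER_Z
    return flags


def outlier_proportions(flags: pd.DataFrame, stratum: str = "") -> OutlierMap:
    """Per-feature fraction of flagged subjects within a stratum."""
    if len(flags) == 0:
        raise ValueError("stratum must be non-empty")
    return OutlierMap(
        stratum=stratum,
        proportions=flags.mean(axis=0),
        n=len(flags),
    )


def _subject_network_matrix(
    flags: pd.DataFrame, parcellation: NetworkParcellation
) -> pd.DataFrame:
    """Boolean subjects x networks: any flagged region in the network."""
    nets = parcellation.networks
    cols = {}
    for net in nets:
        members = [f for f in parcellation.network_features(net) if f in flags.columns]
        if not members:
            continue
        cols[net] = flags[members].any(axis=1)
    return pd.DataFrame(cols, index=flags.index)


def network_outlier_rate(
    flags: pd.DataFrame, parcellation: NetworkParcellation
) -> pd.Series:
    """Per-network fraction of subjects with >= 1 flagged member region."""
    if len(flags) == 0:
        raise ValueError("stratum must be non-empty")
    return _subject_network_matrix(flags, parcellation).mean(axis=0)


def permutation_test(
    case_flags: pd.DataFrame,
    control_flags: pd.DataFrame,
    parcellation: NetworkParcellation,
    n_perm: int = 10_000,
    seed: int = 0,
    per_region: bool = False,
):
    """Group-label permutation test of case outlier rates against controls.

    The observed statistic per network is the case-group subject rate
    (fraction of cases with at least one flagged region in the network).
    Group labels are permuted ``n_perm`` times to build the empirical
    null; p-values use add-one smoothing,
    ``p = (1 + #{null >= observed}) / (n_perm + 1)``, with ties counted
    as exceeding.  With ``per_region=True`` additionally returns
    per-region p-values for the observed outlier proportions, computed
    from the same permutation draws.
    """
    if len(case_flags) == 0 or len(control_flags) == 0:
        raise ValueError("both groups must be non-empty")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives very coarse p-values")
    rng = np.random.default_rng(seed)

    combined = pd.concat([case_flags, control_flags], ignore_index=True)
    n_cases = len(case_flags)
    N = len(combined)

    subj_net = _subject_network_matrix(combined, parcellation)
    nets = list(subj_net.columns)
    obs_net = subj_net.iloc[:n_cases].mean(axis=0).to_numpy()
    A_net = subj_net.to_numpy(float)

    A_reg = combined.to_numpy(float)
    obs_reg = A_reg[:n_cases].mean(axis=0)

    count_net = np.zeros(len(nets))
    count_reg = np.zeros(A_reg.shape[1])
    chunk = 500
    for start in range(0, n_perm, chunk):
        b = min(chunk, n_perm - start)
        # b random case-subsets of size n_cases, without replacement
        keys = rng.random((b, N))
        sel = np.argpartition(keys, n_cases - 1, axis=1)[:, :n_cases]
        null_net = A_net[sel].mean(axis=1)           # (b, n_nets)
        count_net += (null_net >= obs_net - 1e-12).sum(axis=0)
        if per_region:
            null_reg = A_reg[sel].mean(axis=1)
            count_reg += (null_reg >= obs_reg - 1e-12).sum(axis=0)

    p_net = pd.Series((1.0 + count_net) / (n_perm + 1.0), index=nets, name="p")
    if per_region:
        p_reg = pd.Series(
            (1.0 + count_reg) / (n_perm + 1.0), index=combined.columns, name="p"
        )
        return p_net, p_reg
    return p_net


def fdr_correct(p_values) -> np.ndarray | pd.Series:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    arr = np.asarray(p_values, dtype=float)
    if arr.size == 0:
        return arr
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    adj = multipletests(arr, method="fdr_bh")[1]
    if isinstance(p_values, pd.Series):
        return pd.Series(adj, index=p_values.index, name="p_fdr")
    return adj
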