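"""Equidistant cortical depth binning and layer comparability checks.

Depths are fractions of the cortical ribbon (0 = white-matter surface,
1 = pial surface), taken as given — the up/down-sampling that produces
them in a volumetric pipeline is out of scope here and only recorded as
metadata. With three bins, only the deep and superficial bins are analyzed;
the middle bin acts as a partial-volume buffer between them.
"""

from __future__ import annotations

import logging
import warnings
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError

logger = logging.getLogger(__name__)

THREE_BIN_NAMES = ("deep", "middle", "superficial")


def assign_layers(
    depths: np.ndarray | dict[str, float],
    n_bins: int = 3,
    upsample_factor: int = 5,
    roi: str = "roi",
    voxel_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Assign voxels to equidistant depth bins.

    Bin k covers the half-open interval [k/n, (k+1)/n); the top bin is
    closed at depth 1. With ``n_bins=3`` the bins are named deep, middle and
    superficial, and only deep and superficial are flagged ``analyzed``
    (middle is the buffer). Returns a DataFrame indexed by voxel id with
    columns ``depth``, ``bin``, ``analyzed``, ``roi``; ``upsample_factor``
    is kept in ``DataFrame.attrs`` as provenance metadata.
    """
    if isinstance(depths, dict):
        voxel_ids = list(depths.keys())
        depths = np.array(list(depths.values()), dtype=float)
    depths = np.asarray(depths, dtype=float)
    if depths.ndim != 1:
        raise ValidationError("depths must be 1-D")
    if np.any(depths < 0.0) or np.any(depths > 1.0) or not np.all(np.isfinite(depths)):
        raise ValidationError("depths must lie in [0, 1]")
    if n_bins < 2:
        raise ValidationError("n_bins must be >= 2")
    if voxel_ids is None:
        voxel_ids = [f"v{i:05d}" for i in range(len(depths))]
    bin_idx = np.minimum((depths * n_bins).astype(int), n_bins - 1)
    if n_bins == 3:
        names = np.array(THREE_BIN_NAMES)[bin_idx]
        analyzed = names != "middle"
    else:
        names = np.array([f"bin{k}" for k in range(n_bins)])[bin_idx]
        analyzed = np.ones(len(depths), dtype=bool)
    df = pd.DataFrame(
        {"depth": depths, "bin": names, "analyzed": analyzed, "roi": roi},
        index=pd.Index(voxel_ids, name="voxel_id"),
    )
    df.attrs["upsample_factor"] = upsample_factor
    df.attrs["n_bins"] = n_bins
    return df


def layer_voxels(layer_map: pd.DataFrame, layer: str, roi: str | None = None) -> np.ndarray:
    """Integer row indices of the voxels in ``layer`` (optionally one ROI)."""
    mask = (layer_map["bin"] == layer).to_numpy()
    if roi is not None:
        mask &= (layer_map["roi"] == roi).to_numpy()
    return np.flatnonzero(mask)


def check_layer_balance(
    layer_maps: Sequence[pd.DataFrame], rois: Sequence[str] | None = None
) -> pd.DataFrame:
    """Per-ROI voxel counts per bin across subjects plus a two-tailed paired
    t-test of deep vs. superficial counts.

    Takes one layer map per subject (>= 2 subjects). Returns a DataFrame
    with one row per ROI: mean counts per bin and the paired-test columns
    ``t, df, p``. An empty bin raises a warning, not an error.
    """
    from .univariate import paired_ttest

    if len(layer_maps) < 2:
        raise ValidationError("need >= 2 subjects for the paired test")
    if rois is None:
        rois = sorted(set().union(*(set(m["roi"].unique()) for m in layer_maps)))
    rows = []
    for roi in rois:
        counts = {b: [] for b in THREE_BIN_NAMES}
        for m in layer_maps:
            sub = m[m["roi"] == roi]
            for b in THREE_BIN_NAMES:
                c = int((sub["bin"] == b).sum())
                if c == 0:
                    warnings.warn(f"empty bin {b!r} in ROI {roi!r}", stacklevel=2)
                counts[b].append(c)
        deep = np.array(counts["deep"], dtype=float)
        sup = np.array(counts["superficial"], dtype=float)
        res = paired_ttest(deep, sup)
        rows.append(
            {
                "roi": roi,
                "n_deep_mean": deep.mean(),
                "n_middle_mean": float(np.mean(counts["middle"])),
                "n_superficial_mean": sup.mean(),
                "t": res.t,
                "df": res.df,
                "p": res.p,
            }
        )
    return pd.DataFrame(rows).set_index("roi")


def layer_map_to_tsv(layer_map: pd.DataFrame, path) -> None:
    layer_map.reset_index()[["voxel_id", "bin"]].to_csv(path, sep="\t", index=False)


def layer_map_from_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t").set_index("voxel_id")
    df["analyzed"] = df["bin"] != "middle"
    df["depth"] = np.nan
    df["roi"] = df.get("roi", "roi")
    return df
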