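"""Columnar persistence for correlation curves and study outputs."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import CorrelationCurve, ValidationError

__all__ = ["curves_to_frame", "curves_to_csv", "curves_from_csv",
           "curves_to_hdf5", "curves_from_hdf5"]

_COLUMNS = ["sample_id", "sds_cm", "tau_s", "g2", "sigma", "intensity_hz"]


def curves_to_frame(curves: dict[str, list[CorrelationCurve]]) -> pd.DataFrame:
    """Flatten ``{sample_id: [curves]}`` into the long columnar layout."""
    parts = []
    for sample_id, curve_list in curves.items():
        for c in curve_list:
            parts.append(pd.DataFrame({
                "sample_id": sample_id,
                "sds_cm": c.sds,
                "tau_s": c.tau,
                "g2": c.values,
                "sigma": c.sigma if c.sigma is not None else np.nan,
                "intensity_hz": c.intensity if c.intensity is not None else np.nan,
            }))
    if not parts:
        return pd.DataFrame(columns=_COLUMNS)
    return pd.concat(parts, ignore_index=True)[_COLUMNS]


def curves_to_csv(curves: dict[str, list[CorrelationCurve]], path: str) -> None:
    curves_to_frame(curves).to_csv(path, index=False)


def curves_from_csv(path: str) -> dict[str, list[CorrelationCurve]]:
    """Inverse of :func:`curves_to_csv` (intensity-kind curves)."""
    df = pd.read_csv(path)
    missing = set(_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise ValidationError(f"curve CSV missing columns: {sorted(missing)}")
    out: dict[str, list[CorrelationCurve]] = {}
    for (sample_id, sds), group in df.groupby(["sample_id", "sds_cm"], sort=False):
        sigma = group["sigma"].to_numpy() if "sigma" in group else None
        if sigma is not None and np.all(np.isnan(sigma)):
            sigma = None
        intensity = None
        if "intensity_hz" in group and np.isfinite(group["intensity_hz"].iloc[0]):
            intensity = float(group["intensity_hz"].iloc[0])
        curve = CorrelationCurve(
            sds=float(sds), tau=group["tau_s"].to_numpy(),
            values=group["g2"].to_numpy(), kind="intensity",
            sigma=sigma, intensity=intensity)
        out.setdefault(str(sample_id), []).append(curve)
    return out


def curves_to_hdf5(curves: dict[str, list[CorrelationCurve]], path: str) -> None:
    """Single-container storage for large curve grids."""
    import h5py

    df = curves_to_frame(curves)
    with h5py.File(path, "w") as f:
        f.create_dataset("sample_id", data=df["sample_id"].astype(str).to_numpy(dtype="S"))
        for col in _COLUMNS[1:]:
            f.create_dataset(col, data=df[col].to_numpy())


def curves_from_hdf5(path: str) -> dict[str, list[CorrelationCurve]]:
    import h5py

    with h5py.File(path, "r") as f:
        df = pd.DataFrame({
            "sample_id": [s.decode() for s in f["sample_id"][:]],
            **{col: f[col][:] for col in _COLUMNS[1:]},
        })
    out: dict[str, list[CorrelationCurve]] = {}
    for (sample_id, sds), group in df.groupby(["sample_id", "sds_cm"], sort=False):
        sigma = group["sigma"].to_numpy()
        sigma = None if np.all(np.isnan(sigma)) else sigma
        intensity = group["intensity_hz"].iloc[0]
        curve = CorrelationCurve(
            sds=float(sds), tau=group["tau_s"].to_numpy(),
            values=group["g2"].to_numpy(), kind="intensity",
            sigma=sigma,
            intensity=float(intensity) if np.isfinite(intensity) else None)
        out.setdefault(sample_id, []).append(curve)
    return out
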