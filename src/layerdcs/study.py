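"""Experiment orchestration: sample grids, SDS configurations, and studies.

Reproduces the in-silico study design around the layered DCS model:

* a printed physiological parameter grid (8 varied head parameters x 11
  values each, 12 cerebral x 6 scalp flow pairs, 6 separations),
* uniqueness experiments (clean fits, known optics),
* accuracy experiments (correlator-noise-added fits at several averaging
  times with an 8-detector budget),
* Monte Carlo accuracy experiments (analytical fits of slab-MC curves),
* sensitivity experiments (fits with one deliberately mis-assumed optical
  property or thickness).

Every experiment is deterministic given its master seed: per-row noise
sub-seeds are derived with ``numpy.random.SeedSequence`` keyed on the
(sample, configuration, averaging time, repeat, detector) indices.  Results
are long-format pandas DataFrames that summarize into mean/std heatmap
matrices over the separation grid.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .fitting import FitConfig, fit_flows
from .model import CorrelationCurve, HeadModel, ValidationError, g2_layered
from .montecarlo import McRun, mc_g2
from .noise import (CorrelatorScheme, NoiseContext, add_noise, build_scheme,
                    bundle_detectors, decay_rate, scale_intensity, sigma_g2)

__all__ = ["ParameterGrid", "ExperimentSpec", "ResultTable",
           "enumerate_samples", "enumerate_sds_configs",
           "run_uniqueness", "run_accuracy", "run_mc_accuracy",
           "run_sensitivity", "summarize"]

_PARAM_NAMES = ("mua_scalp", "mua_skull", "mua_brain",
                "musp_scalp", "musp_skull", "musp_brain",
                "l_scalp", "l_skull")


@dataclass(frozen=True)
class ParameterGrid:
    """Printed ranges of the varied head parameters and flow indices.

    Each of the 8 head parameters takes ``values_per_parameter`` evenly
    spaced values over its range while the others sit at the median; flow
    pairs combine ``n_cbfi`` evenly spaced cerebral indices with ``n_sbfi``
    evenly spaced scalp-to-cerebral ratios.
    """

    mua_scalp: tuple[float, float] = (0.05, 0.15)
    mua_skull: tuple[float, float] = (0.05, 0.15)
    mua_brain: tuple[float, float] = (0.05, 0.25)
    musp_scalp: tuple[float, float] = (8.0, 12.0)
    musp_skull: tuple[float, float] = (8.0, 12.0)
    musp_brain: tuple[float, float] = (2.0, 6.0)
    l_scalp: tuple[float, float] = (0.15, 0.53)
    l_skull: tuple[float, float] = (0.35, 1.10)
    values_per_parameter: int = 11
    n_cbfi: int = 12
    cbfi_range: tuple[float, float] = (2e-8, 9e-8)
    n_sbfi: int = 6
    sbfi_ratio_range: tuple[float, float] = (1.0 / 8.0, 1.0 / 3.0)
    sds_set: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0)

    def range_of(self, name: str) -> tuple[float, float]:
        if name not in _PARAM_NAMES:
            raise ValidationError(f"unknown parameter {name!r}")
        return getattr(self, name)

    def median_of(self, name: str) -> float:
        lo, hi = self.range_of(name)
        return 0.5 * (lo + hi)

    def values_of(self, name: str) -> np.ndarray:
        lo, hi = self.range_of(name)
        return np.linspace(lo, hi, self.values_per_parameter)

    def cbfi_values(self) -> np.ndarray:
        return np.linspace(*self.cbfi_range, self.n_cbfi)

    def sbfi_ratios(self) -> np.ndarray:
        return np.linspace(*self.sbfi_ratio_range, self.n_sbfi)

    def flow_pairs(self) -> list[tuple[float, float]]:
        """All (SBFi, CBFi) combinations: ratios x cerebral values."""
        return [(float(ratio * cbfi), float(cbfi))
                for cbfi in self.cbfi_values()
                for ratio in self.sbfi_ratios()]

    def head(self, overrides: dict | None = None,
             sbfi: float = 0.0, cbfi: float = 0.0) -> HeadModel:
        """Three-layer head at the medians, with optional overrides."""
        p = {name: self.median_of(name) for name in _PARAM_NAMES}
        if overrides:
            p.update(overrides)
        return HeadModel.three_layer(
            mua=(p["mua_scalp"], p["mua_skull"], p["mua_brain"]),
            musp=(p["musp_scalp"], p["musp_skull"], p["musp_brain"]),
            thickness=(p["l_scalp"], p["l_skull"]),
            bfi=(sbfi, 0.0, cbfi))

    def median_head(self, sbfi: float = 0.0, cbfi: float = 0.0) -> HeadModel:
        return self.head(sbfi=sbfi, cbfi=cbfi)


def enumerate_samples(grid: ParameterGrid) -> pd.DataFrame:
    """All head-parameter/flow combinations of the study design.

    One row per sample: 8 varied parameters x 11 values each (other
    parameters at median; the repeated all-median head is retained, the
    printed totals imply no deduplication) x 72 flow pairs = 6336 rows.
    Each sample is simulated at every separation in ``grid.sds_set``, so the
    number of clean curve specifications is ``len(df) * len(grid.sds_set)``.
    """
    rows = []
    head_idx = 0
    for name in _PARAM_NAMES:
        for value in grid.values_of(name):
            for sbfi, cbfi in grid.flow_pairs():
                rows.append({
                    "sample_id": len(rows),
                    "head_id": head_idx,
                    "varied_param": name,
                    "param_value": float(value),
                    "sbfi_true": sbfi,
                    "cbfi_true": cbfi,
                })
            head_idx += 1
    return pd.DataFrame(rows)


def flow_grid_samples(grid: ParameterGrid) -> pd.DataFrame:
    """The 72 flow pairs on the median head (the slab-MC flow design)."""
    rows = [{"sample_id": i, "head_id": 0, "varied_param": "none",
             "param_value": math.nan, "sbfi_true": sbfi, "cbfi_true": cbfi}
            for i, (sbfi, cbfi) in enumerate(grid.flow_pairs())]
    return pd.DataFrame(rows)


def sample_head(grid: ParameterGrid, row) -> HeadModel:
    """Head model for one row of :func:`enumerate_samples`."""
    if row["varied_param"] == "none":
        return grid.median_head(sbfi=row["sbfi_true"], cbfi=row["cbfi_true"])
    return grid.head(overrides={row["varied_param"]: row["param_value"]},
                     sbfi=row["sbfi_true"], cbfi=row["cbfi_true"])


def enumerate_sds_configs(grid: ParameterGrid,
                          canonical: bool = False) -> list[tuple[float, ...]]:
    """Single separations plus two-separation combinations.

    Ordered pairs (SDS1, SDS2) with SDS1 != SDS2 give 30 combinations from
    the 6-element set; ``canonical=True`` collapses them to the 15 unordered
    pairs used for upper-triangle heatmaps.
    """
    singles = [(r,) for r in grid.sds_set]
    if canonical:
        pairs = [tuple(sorted(p)) for p in
                 itertools.combinations(grid.sds_set, 2)]
    else:
        pairs = [p for p in itertools.permutations(grid.sds_set, 2)]
    return singles + pairs


@dataclass(frozen=True)
class ExperimentSpec:
    """Configuration of one experiment run.

    ``mode`` is one of uniqueness | accuracy | mc_accuracy | sensitivity |
    sensitivity_clean.  With noise on, the detector budget is fixed at 8:
    all eight at a single separation, or 1 + 7 across a pair (the bundle at
    the second separation is averaged).  ``n_samples`` sub-samples the full
    6336-sample grid (seeded) for desk-scale runs; ``None`` uses all.
    """

    mode: str
    sds_configs: tuple[tuple[float, ...], ...]
    noise_on: bool = False
    avg_times: tuple[float, ...] = (1.0, 3.0, 10.0, 30.0)
    reference: tuple[float, float] = (2.5, 20e3)
    beta: float = 0.5
    master_seed: int = 0
    n_samples: int | None = 50
    n_seeds: int = 1
    sample_mode: str = "grid"     # "grid" (full design) | "median_flows"
    perturb_param: str | None = None
    perturb_deltas: tuple[float, ...] = (-0.3, -0.2, -0.1, 0.0, 0.1, 0.2, 0.3)
    grid: ParameterGrid = field(default_factory=ParameterGrid)
    scheme: CorrelatorScheme = field(default_factory=build_scheme)
    fit_config: FitConfig = field(default_factory=FitConfig)

    def __post_init__(self) -> None:
        if self.mode not in ("uniqueness", "accuracy", "mc_accuracy",
                             "sensitivity", "sensitivity_clean"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.noise_on and self.n_seeds < 1:
            raise ValidationError("n_seeds must be >= 1 with noise on")


@dataclass
class ResultTable:
    """Long-format experiment results plus the spec that produced them."""

    rows: pd.DataFrame
    spec: ExperimentSpec

    def summary(self) -> pd.DataFrame:
        """Mean/std of the CBFi percent error per grouping key."""
        keys = ["sds_config"]
        if "t_avg_s" in self.rows and self.rows["t_avg_s"].nunique() > 1:
            keys.append("t_avg_s")
        if "delta" in self.rows:
            keys.append("delta")
        ok = self.rows[self.rows["converged"]]
        return (ok.groupby(keys)["err_cbfi_pct"]
                  .agg(["mean", "std", "count"]).reset_index())


def _config_label(config: tuple[float, ...]) -> str:
    return "+".join(f"{r:g}" for r in config)


def _sub_seed(master: int, *key: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=master, spawn_key=tuple(key))


def _measured_curves(head: HeadModel, config: tuple[float, ...],
                     spec: ExperimentSpec, t_avg: float,
                     seed_key: tuple[int, ...]) -> list[CorrelationCurve]:
    """Simulate what the 8-detector system records for one configuration.

    Clean analytical curves on the correlator grid; with noise on, each
    physical detector receives an independent noise realization of the
    printed sigma(tau) model and detectors sharing a separation are bundled
    (pointwise mean).
    """
    tau = spec.scheme.tau
    clean = {r: g2_layered(head, r, tau, beta=spec.beta) for r in set(config)}
    if not spec.noise_on:
        return [clean[r] for r in config]
    # detector allocation: 8 at a single separation, or 1 + 7 across a pair
    allocation = [8] if len(config) == 1 else [1, 7]
    curves = []
    det_counter = 0
    for r, n_det in zip(config, allocation):
        curve = clean[r]
        intensity = scale_intensity(head, r, spec.reference)
        gamma = decay_rate(curve, spec.beta)
        ctx = NoiseContext(intensity=intensity, avg_time=t_avg,
                           beta=spec.beta, gamma=gamma)
        sigma = sigma_g2(ctx, spec.scheme)
        realizations = []
        for _ in range(n_det):
            seq = _sub_seed(spec.master_seed, *seed_key, det_counter)
            realizations.append(add_noise(curve, sigma, seq))
            det_counter += 1
        curves.append(bundle_detectors(realizations))
    return curves


def _select_samples(spec: ExperimentSpec) -> pd.DataFrame:
    samples = (flow_grid_samples(spec.grid) if spec.sample_mode == "median_flows"
               else enumerate_samples(spec.grid))
    if spec.n_samples is not None and spec.n_samples < len(samples):
        rng = np.random.default_rng(_sub_seed(spec.master_seed, 0))
        idx = rng.choice(len(samples), size=spec.n_samples, replace=False)
        samples = samples.iloc[np.sort(idx)].reset_index(drop=True)
    return samples


def _resume(out_csv, key_cols):
    if out_csv is None:
        return None, set()
    import os
    if os.path.exists(out_csv):
        done = pd.read_csv(out_csv)
        keyed = done[key_cols].copy()
        if "t_avg_s" in keyed:
            keyed["t_avg_s"] = keyed["t_avg_s"].fillna(-1.0)
        keys = set(map(tuple, keyed.itertuples(index=False, name=None)))
        return done, keys
    return None, set()


def _fit_one(curves, assumed_head, spec: ExperimentSpec,
             truth: tuple[float, float]):
    res = fit_flows(curves, assumed_head, spec.fit_config, truth=truth)
    return res


def run_uniqueness(spec: ExperimentSpec, out_csv: str | None = None) -> ResultTable:
    """Clean fits with true optics known: solution-uniqueness survey.

    Samples whose clean-data CBFi error magnitude exceeds 1% are flagged as
    non-uniqueness witnesses (a numerically meaningful reading of "nonzero
    error" under floating point).
    """
    spec = replace(spec, noise_on=False)
    return _run_analytical(spec, out_csv)


def run_accuracy(spec: ExperimentSpec, out_csv: str | None = None) -> ResultTable:
    """Noise-added fits across configurations and averaging times."""
    return _run_analytical(spec, out_csv)


def _run_analytical(spec: ExperimentSpec, out_csv: str | None) -> ResultTable:
    samples = _select_samples(spec)
    t_values = tuple(spec.avg_times) if spec.noise_on else (math.nan,)
    n_seeds = spec.n_seeds if spec.noise_on else 1
    done, done_keys = _resume(out_csv, ["sample_id", "sds_config", "t_avg_s", "seed"])

    rows = []
    n_failed = 0
    for _, sample in samples.iterrows():
        head = sample_head(spec.grid, sample)
        truth = (sample["sbfi_true"], sample["cbfi_true"])
        for ci, config in enumerate(spec.sds_configs):
            for ti, t_avg in enumerate(t_values):
                for rep in range(n_seeds):
                    key = (int(sample["sample_id"]), _config_label(config),
                           -1.0 if math.isnan(t_avg) else float(t_avg), rep)
                    if key in done_keys:
                        continue
                    curves = _measured_curves(
                        head, config, spec, t_avg,
                        seed_key=(int(sample["sample_id"]), ci, ti, rep))
                    try:
                        res = _fit_one(curves, head, spec, truth)
                    except Exception as exc:   # noqa: BLE001 - logged, counted
                        n_failed += 1
                        warnings.warn(f"fit failed for sample "
                                      f"{sample['sample_id']} at {config}: {exc}")
                        continue
                    rows.append({
                        "sample_id": int(sample["sample_id"]),
                        "varied_param": sample["varied_param"],
                        "sds_config": _config_label(config),
                        "sds1": config[0],
                        "sds2": config[1] if len(config) > 1 else config[0],
                        "t_avg_s": float(t_avg),
                        "seed": rep,
                        "sbfi_true": truth[0], "cbfi_true": truth[1],
                        "sbfi_est": res.sbfi_est, "cbfi_est": res.cbfi_est,
                        "chi2": res.chi2,
                        "err_sbfi_pct": res.percent_error_sbfi,
                        "err_cbfi_pct": res.percent_error_cbfi,
                        "converged": res.converged,
                        "nonunique_flag": abs(res.percent_error_cbfi) > 1.0,
                    })
    table = pd.DataFrame(rows)
    if done is not None and len(done):
        table = pd.concat([done, table], ignore_index=True)
    if out_csv is not None:
        table.to_csv(out_csv, index=False)
    if n_failed:
        warnings.warn(f"{n_failed} fits failed and were excluded")
    return ResultTable(rows=table, spec=spec)


def run_mc_accuracy(spec: ExperimentSpec, run: McRun,
                    min_photons: int = 1000,
                    flow_pairs: list[tuple[float, float]] | None = None,
                    out_csv: str | None = None) -> ResultTable:
    """Analytical-model fits of slab Monte Carlo curves.

    Fits every requested flow pair (default: the full 72-pair design) for
    every configuration whose detectors all carry at least ``min_photons``
    records; under-populated configurations are skipped with a warning.
    """
    grid = spec.grid
    radii = list(run.geometry.detector_radii)
    counts = run.counts()
    pairs = grid.flow_pairs() if flow_pairs is None else flow_pairs
    assumed = run.head   # true (median) optics and thicknesses
    rows = []
    for config in spec.sds_configs:
        det_ids = []
        ok = True
        for r in config:
            if r not in radii:
                ok = False
                break
            k = radii.index(r)
            if counts[k] < min_photons:
                ok = False
                break
            det_ids.append(k)
        if not ok:
            warnings.warn(f"configuration {config} skipped: missing or "
                          f"under-populated detector records")
            continue
        for sbfi, cbfi in pairs:
            flows = [0.0] * run.head.n_layers
            flows[0], flows[-1] = sbfi, cbfi
            curves = [mc_g2(run, k, flows, beta=spec.beta, tau=spec.scheme.tau)
                      for k in det_ids]
            res = _fit_one(curves, assumed.with_flows(flows), spec, (sbfi, cbfi))
            rows.append({
                "sample_id": -1,
                "sds_config": _config_label(config),
                "sds1": config[0],
                "sds2": config[1] if len(config) > 1 else config[0],
                "t_avg_s": math.nan, "seed": run.seed,
                "sbfi_true": sbfi, "cbfi_true": cbfi,
                "sbfi_est": res.sbfi_est, "cbfi_est": res.cbfi_est,
                "chi2": res.chi2,
                "err_sbfi_pct": res.percent_error_sbfi,
                "err_cbfi_pct": res.percent_error_cbfi,
                "converged": res.converged,
            })
    table = pd.DataFrame(rows)
    if out_csv is not None:
        table.to_csv(out_csv, index=False)
    return ResultTable(rows=table, spec=spec)


def run_sensitivity(spec: ExperimentSpec,
                    flow_pairs: list[tuple[float, float]] | None = None,
                    t_avg: float = 10.0,
                    out_csv: str | None = None) -> ResultTable:
    """Fits with one deliberately mis-assumed parameter.

    Truth is the median head over the flow-pair design; data are simulated
    from the truth (noise on unless mode is ``sensitivity_clean``), and the
    fitting model sets ``spec.perturb_param`` to (1 + delta) times its true
    value for each delta in ``spec.perturb_deltas``.
    """
    if spec.perturb_param is None:
        raise ValidationError("sensitivity mode needs perturb_param")
    grid = spec.grid
    noise_on = spec.mode != "sensitivity_clean"
    spec = replace(spec, noise_on=noise_on)
    pairs = grid.flow_pairs() if flow_pairs is None else flow_pairs
    name = spec.perturb_param
    median_value = grid.median_of(name)
    rows = []
    for pi, (sbfi, cbfi) in enumerate(pairs):
        true_head = grid.median_head(sbfi=sbfi, cbfi=cbfi)
        for ci, config in enumerate(spec.sds_configs):
            for rep in range(spec.n_seeds if noise_on else 1):
                curves = _measured_curves(true_head, config, spec, t_avg,
                                          seed_key=(pi, ci, 0, rep))
                for delta in spec.perturb_deltas:
                    assumed = grid.head(
                        overrides={name: (1.0 + delta) * median_value},
                        sbfi=sbfi, cbfi=cbfi)
                    res = _fit_one(curves, assumed, spec, (sbfi, cbfi))
                    rows.append({
                        "sample_id": pi,
                        "sds_config": _config_label(config),
                        "sds1": config[0],
                        "sds2": config[1] if len(config) > 1 else config[0],
                        "t_avg_s": t_avg if noise_on else math.nan,
                        "seed": rep,
                        "perturb_param": name, "delta": delta,
                        "sbfi_true": sbfi, "cbfi_true": cbfi,
                        "sbfi_est": res.sbfi_est, "cbfi_est": res.cbfi_est,
                        "chi2": res.chi2,
                        "err_sbfi_pct": res.percent_error_sbfi,
                        "err_cbfi_pct": res.percent_error_cbfi,
                        "converged": res.converged,
                    })
    table = pd.DataFrame(rows)
    if out_csv is not None:
        table.to_csv(out_csv, index=False)
    return ResultTable(rows=table, spec=spec)


def summarize(table: ResultTable) -> dict[str, pd.DataFrame]:
    """Heatmap matrices of the CBFi percent error over the separation grid.

    Returns ``{"mean": ..., "std": ...}`` 6x6 DataFrames indexed by SDS1
    (rows) and SDS2 (columns); the diagonal holds single-separation
    configurations.  Cells without results are NaN (masked).  For
    sensitivity tables the matrices are per perturbation level, keyed
    ``"mean@delta"``.
    """
    rows = table.rows
    if rows.empty:
        raise ValidationError("cannot summarize an empty result table")
    sds_set = table.spec.grid.sds_set

    def matrices(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
        mean = pd.DataFrame(np.nan, index=list(sds_set), columns=list(sds_set))
        std = pd.DataFrame(np.nan, index=list(sds_set), columns=list(sds_set))
        for (s1, s2), group in df.groupby(["sds1", "sds2"]):
            errs = group.loc[group["converged"], "err_cbfi_pct"]
            if len(errs):
                mean.loc[s1, s2] = errs.mean()
                std.loc[s1, s2] = errs.std(ddof=1) if len(errs) > 1 else 0.0
        return mean, std

    out: dict[str, pd.DataFrame] = {}
    if "delta" in rows.columns:
        for delta, group in rows.groupby("delta"):
            m, s = matrices(group)
            out[f"mean@{delta:g}"] = m
            out[f"std@{delta:g}"] = s
    elif "t_avg_s" in rows.columns and rows["t_avg_s"].nunique(dropna=True) > 1:
        for t_avg, group in rows.groupby("t_avg_s", dropna=False):
            m, s = matrices(group)
            out[f"mean@t={t_avg:g}"] = m
            out[f"std@t={t_avg:g}"] = s
    else:
        m, s = matrices(rows)
        out["mean"] = m
        out["std"] = s
    return out
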