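"""Photon Monte Carlo on a layered slab with momentum-transfer recording.

Transports photons through a stack of plane-parallel layers (pencil source,
normal incidence, Henyey-Greenstein scattering, Fresnel reflection at the
top surface, index-matched internal interfaces) and records, for every
photon escaping into a detection annulus, the per-layer pathlength L_i and
the per-layer dimensionless momentum transfer Y_i = sum(1 - cos(theta)).

Absorption is handled analytically through the weight exp(-sum mua_i L_i)
applied when autocorrelation functions are computed from the records, so a
single transport run serves every flow combination and any absorption
perturbation: the unnormalized field autocorrelation is

    G1(r, tau) = (1/Np) * sum_n exp(-(1/3) sum_i Y_ni k0_i^2 <dr^2(tau)>_i)
                        * exp(-sum_i mua_i L_ni),

with Brownian dynamics <dr^2(tau)>_i = 6 D_i tau.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .model import (CorrelationCurve, HeadModel, ValidationError, siegert_g2)

__all__ = ["SlabGeometry", "McRun", "transport_photons", "g1_from_records",
           "mc_g2", "save_records", "load_records"]


@dataclass(frozen=True)
class SlabGeometry:
    """Layered-slab geometry with annular surface detectors.

    ``layer_thicknesses`` lists the finite thicknesses of all but the
    terminal layer (cm).  Detection annuli are centered on the
    ``detector_radii`` with half-width ``detector_capture``; the lateral
    half-width and depth bound emulate a finite sample volume.
    """

    layer_thicknesses: tuple[float, ...] = (0.3, 0.7)
    lateral_halfwidth: float = 10.0
    detector_radii: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0)
    detector_capture: float = 0.05
    depth_bound: float = 10.0

    def __post_init__(self) -> None:
        if any(t <= 0 for t in self.layer_thicknesses):
            raise ValidationError("layer thicknesses must be positive")
        if any(r + self.detector_capture > self.lateral_halfwidth
               for r in self.detector_radii):
            raise ValidationError("detectors must lie within the lateral extent")
        if self.detector_capture <= 0:
            raise ValidationError("detector_capture must be positive")


@dataclass
class McRun:
    """Result of one transport run: per-detected-photon records.

    ``pathlengths`` and ``momentum`` have shape (n_detected, n_layers);
    ``detector_id`` indexes into ``geometry.detector_radii``.  Records are
    flow-independent: re-evaluating G1 for new flow indices or perturbed
    absorption does not require re-transport.
    """

    seed: int
    photons_launched: int
    detector_id: np.ndarray
    pathlengths: np.ndarray
    momentum: np.ndarray
    geometry: SlabGeometry
    head: HeadModel
    warnings: list[str] = field(default_factory=list)

    def counts(self) -> np.ndarray:
        n_det = len(self.geometry.detector_radii)
        return np.bincount(self.detector_id, minlength=n_det)

    def select(self, detector_id: int) -> tuple[np.ndarray, np.ndarray]:
        mask = self.detector_id == detector_id
        return self.pathlengths[mask], self.momentum[mask]


@njit(cache=True, fastmath=True)
def _transport_chunk(seed, n_photons, mus, boundaries, g_hg, n_rel,
                     det_lo, det_hi, lateral, depth_bound, max_record,
                     det_out, l_out, y_out):
    """Transport ``n_photons`` and fill the output record arrays.

    Returns the number of detected photons stored.  ``boundaries`` holds the
    interface depths (cumulative thicknesses) of the non-terminal layers.
    """
    np.random.seed(seed)
    n_layers = mus.size
    n_det = det_lo.size
    count = 0
    crit_sin = 1.0 / n_rel  # total internal reflection limit (sin of angle)
    inv_mus = 1.0 / mus
    l_acc = np.zeros(n_layers)
    y_acc = np.zeros(n_layers)
    for _ in range(n_photons):
        x = 0.0
        y = 0.0
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        layer = 0
        z_lo = 0.0
        z_hi = boundaries[0] if n_layers > 1 else depth_bound
        for j in range(n_layers):
            l_acc[j] = 0.0
            y_acc[j] = 0.0
        u = -math.log(np.random.random())
        alive = True
        steps = 0
        while alive:
            steps += 1
            if steps > 10_000_000:
                alive = False
                break
            mus_l = mus[layer]
            s_free = u * inv_mus[layer]
            # distance to the layer boundary along the flight direction
            if uz > 0.0:
                d_b = (z_hi - z) / uz
            elif uz < 0.0:
                d_b = (z_lo - z) / uz
            else:
                d_b = 1e30
            if s_free < d_b:
                # scattering event inside the current layer
                x += ux * s_free
                y += uy * s_free
                z += uz * s_free
                l_acc[layer] += s_free
                if abs(x) > lateral or abs(y) > lateral:
                    alive = False
                    break
                if g_hg > 0.0:
                    tmp = (1.0 - g_hg * g_hg) / (1.0 - g_hg + 2.0 * g_hg * np.random.random())
                    ct = (1.0 + g_hg * g_hg - tmp * tmp) / (2.0 * g_hg)
                else:
                    ct = 1.0 - 2.0 * np.random.random()
                if ct > 1.0:
                    ct = 1.0
                elif ct < -1.0:
                    ct = -1.0
                y_acc[layer] += 1.0 - ct
                st = math.sqrt(1.0 - ct * ct)
                # uniform azimuth via Marsaglia rejection (avoids cos/sin)
                while True:
                    v1 = 2.0 * np.random.random() - 1.0
                    v2 = 2.0 * np.random.random() - 1.0
                    s_2 = v1 * v1 + v2 * v2
                    if 0.0 < s_2 < 1.0:
                        break
                cp = (v1 * v1 - v2 * v2) / s_2
                sp = 2.0 * v1 * v2 / s_2
                if abs(uz) > 0.99999:
                    ux = st * cp
                    uy = st * sp
                    uz = ct if uz >= 0.0 else -ct
                else:
                    den = math.sqrt(1.0 - uz * uz)
                    ux_n = st * (ux * uz * cp - uy * sp) / den + ux * ct
                    uy_n = st * (uy * uz * cp + ux * sp) / den + uy * ct
                    uz_n = -den * st * cp + uz * ct
                    ux = ux_n
                    uy = uy_n
                    uz = uz_n
                u = -math.log(np.random.random())
            else:
                # move to the boundary
                x += ux * d_b
                y += uy * d_b
                z += uz * d_b
                l_acc[layer] += d_b
                u -= d_b * mus_l
                if abs(x) > lateral or abs(y) > lateral:
                    alive = False
                    break
                if uz < 0.0 and layer == 0:
                    # top surface: Fresnel reflection or escape
                    z = 0.0
                    ci = -uz
                    si = math.sqrt(max(0.0, 1.0 - ci * ci))
                    refl = 1.0
                    if si < crit_sin:
                        stt = n_rel * si
                        ctt = math.sqrt(1.0 - stt * stt)
                        rs = (n_rel * ci - ctt) / (n_rel * ci + ctt)
                        rp = (ci - n_rel * ctt) / (ci + n_rel * ctt)
                        refl = 0.5 * (rs * rs + rp * rp)
                    if np.random.random() < refl:
                        uz = -uz
                    else:
                        rho = math.sqrt(x * x + y * y)
                        for k in range(n_det):
                            if det_lo[k] <= rho <= det_hi[k]:
                                if count < max_record:
                                    det_out[count] = k
                                    for j in range(n_layers):
                                        l_out[count, j] = l_acc[j]
                                        y_out[count, j] = y_acc[j]
                                    count += 1
                                break
                        alive = False
                elif uz > 0.0 and layer == n_layers - 1:
                    # bottom depth bound
                    alive = False
                else:
                    if uz > 0.0:
                        z = boundaries[layer]
                        layer += 1
                    else:
                        layer -= 1
                        z = boundaries[layer]
                    z_lo = boundaries[layer - 1] if layer > 0 else 0.0
                    z_hi = (boundaries[layer] if layer < n_layers - 1
                            else depth_bound)
        # photon finished
    return count


def transport_photons(geometry: SlabGeometry, head: HeadModel, n_photons: int,
                      seed: int, target_detected: int | None = None,
                      target_detectors: tuple[int, ...] | None = None,
                      chunk_size: int = 500_000) -> McRun:
    """Run seeded photon transport through the layered slab.

    Launches up to ``n_photons``; if ``target_detected`` is given, stops as
    soon as every monitored detector (``target_detectors``, default all) has
    at least that many records -- the launch count then acts as a cap.
    Detectors that end up with zero records are reported in
    ``McRun.warnings`` and via ``warnings.warn`` -- never silently.
    """
    if n_photons < 1:
        raise ValidationError("n_photons must be >= 1")
    if head.n_layers != len(geometry.layer_thicknesses) + 1:
        raise ValidationError("geometry layer count must match the head model")
    g_vals = {lay.anisotropy for lay in head.layers}
    n_vals = {lay.refractive_index for lay in head.layers}
    if len(g_vals) != 1 or len(n_vals) != 1:
        raise ValidationError(
            "transport assumes a single anisotropy and refractive index "
            "across layers (index-matched internal interfaces)")
    g_hg = g_vals.pop()
    n_rel = n_vals.pop()

    mus = np.array([lay.musp / (1.0 - lay.anisotropy) for lay in head.layers])
    boundaries = np.cumsum(np.asarray(geometry.layer_thicknesses, dtype=float))
    radii = np.asarray(geometry.detector_radii, dtype=float)
    det_lo = radii - geometry.detector_capture
    det_hi = radii + geometry.detector_capture

    seed_seq = np.random.SeedSequence(seed)
    det_parts, l_parts, y_parts = [], [], []
    launched = 0
    n_layers = head.n_layers
    while launched < n_photons:
        n_chunk = min(chunk_size, n_photons - launched)
        max_rec = n_chunk  # worst case every photon detected
        det_out = np.empty(max_rec, dtype=np.int32)
        l_out = np.empty((max_rec, n_layers))
        y_out = np.empty((max_rec, n_layers))
        chunk_seed = int(seed_seq.spawn(1)[0].generate_state(1)[0] % (2 ** 31))
        count = _transport_chunk(chunk_seed, n_chunk, mus, boundaries, g_hg,
                                 n_rel, det_lo, det_hi,
                                 geometry.lateral_halfwidth,
                                 geometry.depth_bound, max_rec,
                                 det_out, l_out, y_out)
        det_parts.append(det_out[:count].copy())
        l_parts.append(l_out[:count].copy())
        y_parts.append(y_out[:count].copy())
        launched += n_chunk
        if target_detected is not None:
            counts = np.bincount(np.concatenate(det_parts), minlength=radii.size)
            watch = (counts if target_detectors is None
                     else counts[list(target_detectors)])
            if watch.size and watch.min() >= target_detected:
                break

    det_id = np.concatenate(det_parts) if det_parts else np.empty(0, np.int32)
    run = McRun(seed=seed, photons_launched=launched,
                detector_id=det_id,
                pathlengths=np.concatenate(l_parts) if l_parts else np.empty((0, n_layers)),
                momentum=np.concatenate(y_parts) if y_parts else np.empty((0, n_layers)),
                geometry=geometry, head=head)
    counts = run.counts()
    for k, c in enumerate(counts):
        if c == 0:
            msg = (f"detector {k} at r={radii[k]} cm detected zero photons "
                   f"after launching {launched}")
            run.warnings.append(msg)
            warnings.warn(msg)
    return run


def g1_from_records(run: McRun, detector_id: int, bfi_per_layer,
                    mua_per_layer=None, k0=None,
                    tau: np.ndarray | None = None) -> CorrelationCurve:
    """Normalized field autocorrelation from photon records (Brownian dynamics).

    ``bfi_per_layer`` holds the effective diffusion coefficients D_i in
    cm^2/s; ``mua_per_layer`` and ``k0`` default to the head model the run
    was transported with.  The curve is G1(tau)/G1(0), where G1(0) is the
    mean analytic absorption weight.
    """
    if tau is None:
        raise ValidationError("tau grid is required")
    tau = np.asarray(tau, dtype=float)
    bfi = np.asarray(bfi_per_layer, dtype=float)
    mua = (np.array([lay.mua for lay in run.head.layers])
           if mua_per_layer is None else np.asarray(mua_per_layer, dtype=float))
    k0_arr = run.head.k0 if k0 is None else np.asarray(k0, dtype=float) * np.ones(run.head.n_layers)
    L, Y = run.select(detector_id)
    if L.shape[0] == 0:
        raise ValidationError(f"no photon records at detector {detector_id}")
    w = np.exp(-L @ mua)                      # analytic absorption weight
    # (1/3) * sum_i Y_i k0_i^2 * 6 D_i tau  =  (2 sum_i Y_i k0_i^2 D_i) tau
    q = 2.0 * (Y @ (k0_arr ** 2 * bfi))
    g1_tau = (w @ np.exp(-np.outer(q, tau))) / w.sum()
    sds = float(run.geometry.detector_radii[detector_id])
    return CorrelationCurve(sds=sds, tau=tau, values=g1_tau, kind="field")


def mc_g2(run: McRun, detector_id: int, bfi_per_layer, beta: float = 0.5,
          mua_per_layer=None, k0=None,
          tau: np.ndarray | None = None) -> CorrelationCurve:
    """Intensity autocorrelation from records via the Siegert relation."""
    g1 = g1_from_records(run, detector_id, bfi_per_layer,
                         mua_per_layer=mua_per_layer, k0=k0, tau=tau)
    return siegert_g2(g1, beta)


# --------------------------------------------------------------------------
# Persistence
# --------------------------------------------------------------------------

def save_records(run: McRun, path: str) -> None:
    """Persist photon records and geometry/optics metadata to HDF5."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("detector_id", data=run.detector_id)
        f.create_dataset("pathlengths", data=run.pathlengths)
        f.create_dataset("momentum", data=run.momentum)
        f.attrs["seed"] = run.seed
        f.attrs["photons_launched"] = run.photons_launched
        f.attrs["layer_thicknesses"] = list(run.geometry.layer_thicknesses)
        f.attrs["detector_radii"] = list(run.geometry.detector_radii)
        f.attrs["detector_capture"] = run.geometry.detector_capture
        f.attrs["lateral_halfwidth"] = run.geometry.lateral_halfwidth
        f.attrs["depth_bound"] = run.geometry.depth_bound
        f.attrs["head_config"] = run.head.to_text()


def load_records(path: str) -> McRun:
    """Load photon records saved by :func:`save_records`."""
    import h5py

    with h5py.File(path, "r") as f:
        geometry = SlabGeometry(
            layer_thicknesses=tuple(f.attrs["layer_thicknesses"]),
            lateral_halfwidth=float(f.attrs["lateral_halfwidth"]),
            detector_radii=tuple(f.attrs["detector_radii"]),
            detector_capture=float(f.attrs["detector_capture"]),
            depth_bound=float(f.attrs["depth_bound"]))
        head = HeadModel.from_text(str(f.attrs["head_config"]))
        run = McRun(seed=int(f.attrs["seed"]),
                    photons_launched=int(f.attrs["photons_launched"]),
                    detector_id=f["detector_id"][:],
                    pathlengths=f["pathlengths"][:],
                    momentum=f["momentum"][:],
                    geometry=geometry, head=head)
    if run.pathlengths.shape[1] != head.n_layers:
        raise ValidationError("record layer count does not match head model")
    return run
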