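"""Iterative in situ PSF learning from blinking single-molecule data.

The loop: (1) take candidate emitter ROIs, (2) localize them with the
current PSF model, (3) select a quality-filtered subset stratified across
the axial range (defocused emitters carry most of the aberration
information), (4) re-estimate the pupil jointly from the subset. Steps 2-4
repeat until the pupil stops changing; with good signal two rounds usually
suffice.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .engine import (FourPiFitProblem, PupilFitProblem, default_fit_mode_indices,
                     fit)
from .forward import FieldDependentModel
from .localize import ZernikePSFModel, mle_localize
from .loss import LossSpec
from .preprocess import ROIDataset
from .psf import field_factors
from .pupil import (ComplexPupil, OpticalConfig, PupilGrid, apodization,
                    build_pupil_grid, cfft2)
from .zernike import ZernikeBasis

log = logging.getLogger(__name__)

__all__ = ["InsituConfig", "InsituResult", "initial_model", "select_emitters",
           "run_insitu", "run_insitu_multichannel", "run_insitu_fd",
           "localize_dataset", "rms_wavefront_error"]


@dataclass
class InsituConfig:
    """Controls of the in situ learning loop."""

    n_emitters_target: int = 2000
    z_bins: int = 10
    z_range: tuple[float, float] = (-600.0, 600.0)
    defocus_cutoff: float = 300.0      # |z| above which an emitter is "defocused"
    defocus_fraction: float = 0.5
    max_rounds: int = 6
    tol_rad: float = 0.01              # RMS pupil-phase change between rounds
    min_photons: float = 500.0
    max_background: float = 200.0
    drop_worst_ll: float = 0.10
    max_iter_fit: int = 150
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.defocus_fraction <= 1:
            raise ValueError("defocus_fraction must be in [0, 1]")
        if self.max_rounds < 1:
            raise ValueError("max_rounds must be >= 1")


@dataclass
class InsituResult:
    pupil: ComplexPupil
    coeffs: np.ndarray
    basis: ZernikeBasis
    rounds: pd.DataFrame
    converged: bool
    diverged: bool = False
    fit_values: dict = dc_field(default_factory=dict)


def initial_model(grid: PupilGrid, basis: ZernikeBasis,
                  seed_aberration: dict | None = None,
                  phase_image: np.ndarray | None = None) -> np.ndarray:
    """Initial full coefficient vector (or a pass-through designed phase).

    With no seed this is the unaberrated (flat, Strehl 1) pupil; astigmatic
    systems should seed their known astigmatism so the z-sign is fixed from
    round one. A designed phase image (e.g. a Tetrapod mask) may be passed
    through instead and is projected onto the basis.
    """
    coeffs = np.zeros(basis.n_modes)
    if phase_image is not None:
        # least-squares projection onto the (discretely non-orthogonal)
        # sampled modes, restricted to the aperture
        ap = grid.aperture
        a = basis.values[:, ap].T
        coeffs, *_ = np.linalg.lstsq(a, phase_image[ap], rcond=None)
        return coeffs
    if seed_aberration:
        for nm, v in seed_aberration.items():
            coeffs[basis.index_of(*nm)] = v
    return coeffs


def localize_dataset(rois: np.ndarray, model: ZernikePSFModel) -> pd.DataFrame:
    """Localize every (single-frame) ROI with the given model."""
    rows = []
    for i, roi in enumerate(rois):
        img = roi[0] if roi.ndim == 3 else roi
        loc = mle_localize(img, model)
        rows.append({"index": i, "x": loc.x, "y": loc.y, "z": loc.z,
                     "photons": loc.photons, "background": loc.background,
                     "log_likelihood": loc.log_likelihood,
                     "converged": loc.converged})
    return pd.DataFrame(rows)


def select_emitters(localizations: pd.DataFrame, cfg: InsituConfig
                    ) -> np.ndarray:
    """Quality-filter then stratify localizations across the axial range.

    Equal-count sampling over ``z_bins`` bins of the configured z-range keeps
    the z coverage approximately uniform; if fewer than the target fraction
    of the subset is defocused (|z| > cutoff), defocused emitters are topped
    up. Deterministic under the config seed. Raises when fewer than two bins
    are populated ("z-range not spanned").
    """
    if len(localizations) == 0:
        raise ValueError("no localizations to select from")
    rng = np.random.default_rng(cfg.seed)
    df = localizations
    ok = ((df["photons"] >= cfg.min_photons)
          & (df["background"] <= cfg.max_background))
    if ok.sum() > 10:
        thresh = np.quantile(df.loc[ok, "log_likelihood"], cfg.drop_worst_ll)
        ok = ok & (df["log_likelihood"] >= thresh)
    df = df[ok]
    if len(df) == 0:
        raise ValueError("all localizations removed by quality filters")
    edges = np.linspace(cfg.z_range[0], cfg.z_range[1], cfg.z_bins + 1)
    which = np.digitize(df["z"], edges) - 1
    populated = [b for b in range(cfg.z_bins)
                 if np.sum(which == b) > 0]
    if len(populated) < 2:
        raise ValueError("z-range not spanned: emitters concentrate in "
                         f"{len(populated)} of {cfg.z_bins} z-bins")
    for b in range(cfg.z_bins):
        if b not in populated:
            warnings.warn(f"z-bin {b} empty", RuntimeWarning, stacklevel=2)
    per_bin = max(1, cfg.n_emitters_target // cfg.z_bins)
    chosen = []
    for b in populated:
        idx = df.index[which == b].to_numpy()
        take = min(per_bin, len(idx))
        chosen.append(rng.choice(idx, size=take, replace=False))
    sel = np.concatenate(chosen)
    # defocus top-up: add k defocused so (n_def + k)/(n + k) >= fraction
    zsel = df.loc[sel, "z"].abs()
    n_def = int(np.sum(zsel > cfg.defocus_cutoff))
    f = cfg.defocus_fraction
    need = 0 if f >= 1.0 else int(np.ceil(
        max(0.0, (f * len(sel) - n_def) / (1.0 - f))))
    if need > 0:
        pool = df.index[(df["z"].abs() > cfg.defocus_cutoff)
                        & ~df.index.isin(sel)].to_numpy()
        if len(pool):
            sel = np.concatenate([sel,
                                  rng.choice(pool, size=min(need, len(pool)),
                                             replace=False)])
    return np.asarray(sorted(set(int(i) for i in sel)))


def rms_wavefront_error(coeffs_a: np.ndarray, coeffs_b: np.ndarray,
                        basis: ZernikeBasis, wavelength: float,
                        exclude_gauge: bool = True) -> float:
    """RMS wavefront difference between two Zernike pupils, in nm.

    With unit-RMS modes the aperture RMS of the phase difference is the
    Euclidean norm of the coefficient difference; piston/tip/tilt/defocus are
    excluded by default because they are gauge-degenerate with a global
    phase and the emitters' x, y, z. Radians convert to nm by
    lambda / (2 pi).
    """
    d = np.asarray(coeffs_a, float) - np.asarray(coeffs_b, float)
    if exclude_gauge:
        keep = default_fit_mode_indices(basis)
        d = d[keep]
    return float(np.linalg.norm(d) * wavelength / (2 * np.pi))


def run_insitu(data, cfg: InsituConfig, optics: OpticalConfig,
               seed_aberration: dict | None = None,
               vectorial: bool = True, max_radial_order: int = 8,
               fit_mode_idx: np.ndarray | None = None) -> InsituResult:
    """The iterative in situ PSF learning loop on single-molecule ROIs.

    ``data`` is a :class:`ROIDataset` (kind blinking-emitter) or a raw
    (n, R, R) array in photons. Returns the learned Zernike pupil and
    per-round diagnostics; stops when the RMS pupil-phase change falls below
    ``cfg.tol_rad`` or after ``cfg.max_rounds``. If the joint-fit loss
    increases between rounds the best round is returned with the divergence
    flag set.
    """
    rois = data.rois if isinstance(data, ROIDataset) else np.asarray(data)
    if rois.ndim == 3:
        rois = rois[:, None]
    grid = build_pupil_grid(optics)
    basis = grid.zernike_basis(max_radial_order=max_radial_order)
    factors = field_factors(grid, optics, vectorial=vectorial)
    mag = apodization(grid)
    coeffs = initial_model(grid, basis, seed_aberration)
    if fit_mode_idx is None:
        fit_mode_idx = default_fit_mode_indices(basis)
    fixed = np.zeros(basis.n_modes)

    rounds = []
    prev_change = np.inf
    diverged = False
    converged = False
    cur_fit = coeffs[fit_mode_idx].copy()
    prev_fit = cur_fit.copy()
    fit_values = {}
    for rnd in range(1, cfg.max_rounds + 1):
        full = fixed.copy()
        full[fit_mode_idx] += cur_fit
        pupil = ComplexPupil(magnitude=mag,
                             phase=np.where(grid.aperture,
                                            basis.compose(full), 0.0),
                             coeff_phase=full, aperture=grid.aperture)
        model = ZernikePSFModel(pupil, grid, factors=factors)
        locs = localize_dataset(rois, model)
        sel = select_emitters(locs, cfg)
        sub = rois[sel]
        sl = locs.loc[sel]
        problem = PupilFitProblem(sub, grid, basis, factors, magnitude=mag,
                                  fit_mode_idx=fit_mode_idx,
                                  loss_spec=LossSpec(data_term="poisson"))
        ps = problem.make_params(coeffs0=cur_fit,
                                 x0=sl["x"].to_numpy(),
                                 y0=sl["y"].to_numpy(),
                                 z0=sl["z"].to_numpy(),
                                 photons0=np.maximum(sl["photons"], 50),
                                 background0=np.maximum(sl["background"],
                                                        1e-2))
        res = fit(problem, ps, max_iter=cfg.max_iter_fit)
        new_fit = res.values["coeffs"]
        change = float(np.linalg.norm(new_fit - cur_fit))
        rounds.append({"round": rnd, "n_selected": len(sel),
                       "loss": res.final_loss, "rms_change_rad": change,
                       "n_iter": res.n_iter})
        log.info("in situ round %d: %d emitters, loss %.6g, change %.4g rad",
                 rnd, len(sel), res.final_loss, change)
        # each round fits a different emitter subset, so losses are not
        # comparable across rounds; convergence/divergence is judged on the
        # model change instead
        if change > 1.5 * prev_change and change > cfg.tol_rad:
            diverged = True
            cur_fit = prev_fit
            break
        prev_change = change
        prev_fit = cur_fit
        cur_fit = new_fit
        fit_values = res.values
        if change < cfg.tol_rad:
            converged = True
            break

    full = fixed.copy()
    full[fit_mode_idx] += cur_fit
    # re-attach the gauge-free seed modes for reporting (tip/tilt/defocus
    # stay zero; astigmatism etc. live inside the fitted set)
    pupil = ComplexPupil(magnitude=mag,
                         phase=np.where(grid.aperture, basis.compose(full),
                                        0.0),
                         coeff_phase=full, aperture=grid.aperture)
    return InsituResult(pupil=pupil, coeffs=full, basis=basis,
                        rounds=pd.DataFrame(rounds), converged=converged,
                        diverged=diverged, fit_values=fit_values)


# ---------------------------------------------------------------------------
# 4Pi multi-channel in situ learning


def _scan_init_4pi(data: np.ndarray, problem: FourPiFitProblem,
                   z_grid: np.ndarray, n_phi: int = 8):
    """Coarse (z, phi) initialization per ROI from on-axis model templates."""
    grid = problem.grid
    phis = np.linspace(0, 2 * np.pi, n_phi, endpoint=False)
    phi_t = np.tensordot(np.zeros(len(problem.fit_idx)), problem.zfit,
                         axes=(0, 0))
    templates = []
    for z in z_grid:
        defoc = 2 * np.pi * grid.kz * z
        et = cfft2(problem.magnitude * np.exp(1j * (phi_t + defoc)))
        eb = cfft2(problem.magnitude * np.exp(1j * (phi_t - defoc)))
        per_phi = []
        for ph in phis:
            chans = []
            for d in problem.delta:
                f = et + np.exp(1j * (ph + d)) * eb
                psf = np.abs(f) ** 2 / problem.i0
                from .forward import pixel_integrate
                chans.append(pixel_integrate(psf, problem.os))
            per_phi.append(np.stack(chans))
        templates.append(per_phi)
    z0 = np.empty(len(data))
    p0 = np.empty(len(data))
    for i, d in enumerate(data):
        b = max(float(np.median(d)), 1e-2)
        s = max(float(d.sum() - b * d.size), 10.0)
        best = None
        for zi, z in enumerate(z_grid):
            for pi, ph in enumerate(phis):
                mu = np.maximum(templates[zi][pi] * s + b, 1e-9)
                val = float(np.sum(mu - d * np.log(mu)))
                if best is None or val < best[0]:
                    best = (val, z, ph)
        z0[i], p0[i] = best[1], best[2]
    return z0, p0


def run_insitu_multichannel(data: np.ndarray, cfg: InsituConfig,
                            optics: OpticalConfig,
                            channel_phases: Sequence[float] | None = None,
                            seed_aberration: dict | None = None,
                            max_radial_order: int = 6,
                            fit_mode_idx: np.ndarray | None = None,
                            link_arms: bool = False,
                            fit_channel_offsets: bool = True,
                            n_rounds: int = 2):
    """Joint 4Pi in situ learning: arm pupils + per-emitter (x, y, z, phi).

    Higher-order Zernikes can be linked between the arms (``link_arms``);
    tip/tilt/defocus are never fitted as pupil modes because the per-emitter
    x, y, z and per-channel lateral offsets carry those degrees of freedom.
    A relative piston phase between the arms is absorbed by the per-emitter
    interference phase. Channel registration is refined as per-channel
    lateral offsets.
    """
    data = np.asarray(data, float)
    if data.ndim != 4:
        raise ValueError("multichannel data must be (n_roi, C, R, R)")
    grid = build_pupil_grid(optics)
    basis = grid.zernike_basis(max_radial_order=max_radial_order)
    problem = FourPiFitProblem(data, grid, basis,
                               fit_mode_idx=fit_mode_idx,
                               channel_phases=channel_phases,
                               link_arms=link_arms,
                               fit_channel_offsets=fit_channel_offsets)
    seed_fit = np.zeros(len(problem.fit_idx))
    if seed_aberration:
        full = initial_model(grid, basis, seed_aberration)
        seed_fit = full[problem.fit_idx]
    zlo, zhi = cfg.z_range
    z_grid = np.linspace(zlo * 0.9, zhi * 0.9, 13)
    z0, p0 = _scan_init_4pi(data, problem, z_grid)
    ct, cb = seed_fit.copy(), seed_fit.copy()
    res = None
    for _ in range(max(1, n_rounds)):
        ps = problem.make_params(coeffs_top0=ct, coeffs_bottom0=cb,
                                 z0=z0, phi0=p0)
        res = fit(problem, ps, max_iter=cfg.max_iter_fit)
        ct = res.values["coeffs_top"]
        cb = res.values["coeffs_bottom"]
        z0 = res.values["z"]
        p0 = res.values["phi"]
    pup_t, pup_b = problem.result_pupils(res.values)
    return {"pupil_top": pup_t, "pupil_bottom": pup_b,
            "coeffs_top": ct, "coeffs_bottom": cb,
            "fit_idx": problem.fit_idx, "basis": basis,
            "channel_offsets": res.values.get("channel_offset"),
            "values": res.values, "result": res}


# ---------------------------------------------------------------------------
# Field-dependent in situ learning


def run_insitu_fd(data: ROIDataset, cfg: InsituConfig, optics: OpticalConfig,
                  fov_size: int, map_resolution: int = 8,
                  seed_aberration: dict | None = None,
                  vectorial: bool = False, max_radial_order: int = 4,
                  fd_smooth_weight: float = 1e-4,
                  max_iter: int | None = None) -> dict:
    """Learn field-dependent aberration maps from FOV-distributed emitters.

    Each emitter's Zernike coefficients are bilinear interpolations of
    per-mode maps at its FOV position; the maps are optimized globally over
    all emitters with a first-difference smoothness penalty, so subregions
    without emitters still receive finite, smooth values.
    """
    rois = data.rois
    grid = build_pupil_grid(optics)
    basis = grid.zernike_basis(max_radial_order=max_radial_order)
    factors = field_factors(grid, optics, vectorial=vectorial)
    mag = apodization(grid)
    fit_idx = default_fit_mode_indices(basis)
    fixed = initial_model(grid, basis, seed_aberration)
    pitch = fov_size / map_resolution
    fd = FieldDependentModel(
        maps=np.zeros((len(fit_idx), map_resolution, map_resolution)),
        map_pitch=pitch, modes=[basis.modes[i] for i in fit_idx])
    fov = data.fov_centers().astype(float)
    # coverage check
    occupied = set()
    for (x, y) in fov:
        occupied.add((min(int(y // pitch), map_resolution - 1),
                      min(int(x // pitch), map_resolution - 1)))
    n_empty = map_resolution ** 2 - len(occupied)
    if n_empty > 0.5 * map_resolution ** 2:
        warnings.warn(f"{n_empty} of {map_resolution ** 2} FOV subregions "
                      "contain no emitter", RuntimeWarning, stacklevel=2)

    pupil = ComplexPupil(magnitude=mag,
                         phase=np.where(grid.aperture, basis.compose(fixed),
                                        0.0),
                         coeff_phase=fixed, aperture=grid.aperture)
    model = ZernikePSFModel(pupil, grid, factors=factors)
    locs = localize_dataset(rois, model)
    problem = PupilFitProblem(
        rois, grid, basis, factors, magnitude=mag, fit_mode_idx=fit_idx,
        fixed_coeffs=fixed, fd_model=fd, fov_positions=fov,
        loss_spec=LossSpec(data_term="poisson",
                           fd_smooth_weight=fd_smooth_weight))
    ps = problem.make_params(x0=locs["x"].to_numpy(),
                             y0=locs["y"].to_numpy(),
                             z0=locs["z"].to_numpy(),
                             photons0=np.maximum(locs["photons"], 50),
                             background0=np.maximum(locs["background"], 1e-2))
    res = fit(problem, ps, max_iter=max_iter or cfg.max_iter_fit)
    fd_out = FieldDependentModel(maps=res.values["fd_maps"], map_pitch=pitch,
                                 modes=fd.modes)
    return {"fd_model": fd_out, "basis": basis, "fit_idx": fit_idx,
            "fixed_coeffs": fixed, "result": res}
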