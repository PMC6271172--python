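"""Pixel-wise nonlinear regression of decay models to bleach stacks.

Every pixel of a time-lapse bleach stack is fitted with a decay-plus-offset
model by bounded trust-region least squares; the fitted parameters are
assembled into 2-D maps, from which three variants of the time-integrated
emission (TiEm) image are computed:

* ``formula``: amplitude x time constant (for the bi-exponential model the
  sum of both such products; for the stretched exponential the closed-form
  integral A*tau*Gamma(1 + 1/h)).  This is the quantity that cancels both
  the autofluorescence background B and illumination shading;
* ``sum_minus_background``: frame-interval-weighted sum of the reconstructed
  model frames without B;
* ``sum_plus_background``: the same with B included, which grows linearly
  with acquisition time and therefore overestimates the true TiEm.

Fitting is fully deterministic: initialization is computed from the trace
(no random restarts), so identical input yields bit-identical maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.special import gamma as gamma_fn

logger = logging.getLogger(__name__)

__all__ = [
    "BleachStack",
    "DecayModelSpec",
    "MONOEXP",
    "BIEXP",
    "STREXP",
    "MODELS",
    "FitOptions",
    "DecayFit",
    "ParameterMaps",
    "fit_pixel",
    "fit_stack",
    "tiem_maps",
    "cumulative_integral_stack",
    "select_model",
    "region_statistics",
]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class BleachStack:
    """T x Y x X intensity stack with uniform frame interval ``dt`` (s).

    The first frame is taken at ``t0`` (default 0 s, i.e. zero accumulated
    exposure), so frame i sits at t_i = t0 + i*dt.  At least 4 frames are
    required to fit the three-parameter mono-exponential-plus-offset model
    with one residual degree of freedom.
    """

    data: np.ndarray
    dt: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"stack must be T x Y x X, got shape {self.data.shape}")
        if self.data.shape[0] < 4:
            raise ValueError("stack needs at least 4 frames for decay fitting")
        if self.dt <= 0:
            raise ValueError("frame interval dt must be > 0")
        if np.any(np.asarray(self.data) < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n_frames)


@dataclass(frozen=True)
class DecayModelSpec:
    """A named decay model with its parameters and bounds.

    ``param_names`` excludes nothing — the constant background B is always
    the last parameter.  ``n_params`` counts all fitted parameters.
    """

    name: str
    param_names: tuple[str, ...]

    @property
    def n_params(self) -> int:
        return len(self.param_names)


MONOEXP = DecayModelSpec("monoexp", ("amplitude", "tau", "background"))
BIEXP = DecayModelSpec("biexp", ("amplitude1", "tau1", "amplitude2", "tau2", "background"))
STREXP = DecayModelSpec("strexp", ("amplitude", "tau", "h", "background"))

MODELS: dict[str, DecayModelSpec] = {m.name: m for m in (MONOEXP, BIEXP, STREXP)}

_H_MAX = 3.0
_TAU_MIN = 1e-12


@dataclass(frozen=True)
class FitOptions:
    """Options for pixel and stack fitting.

    max_iter/xtol feed the bounded trust-region optimizer; ``mask_quantile``
    excludes pixels whose first-frame intensity falls below that quantile of
    the first frame (an absolute ``min_intensity`` may be given instead);
    ``tau_ratio_floor`` flags bi-exponential fits whose two time constants
    are closer than this ratio as effectively mono-exponential.
    """

    max_iter: int = 200
    xtol: float = 1e-10
    mask_quantile: float = 0.01
    min_intensity: float | None = None
    tau_ratio_floor: float = 1.5


@dataclass
class DecayFit:
    """Result of fitting one pixel trace."""

    model: str
    params: dict[str, float]
    rmse: float
    chi2: float
    converged: bool
    n_iter: int
    degenerate: bool = False
    flags: tuple[str, ...] = ()


@dataclass
class ParameterMaps:
    """Per-parameter 2-D maps plus goodness-of-fit and convergence masks.

    Masked (unfitted) pixels carry NaN in every float map, distinguishable
    from fitted zeros; ``mask`` is True where a fit was attempted.
    """

    model: str
    maps: dict[str, np.ndarray]
    rmse: np.ndarray
    chi2: np.ndarray
    converged: np.ndarray
    mask: np.ndarray
    metadata: dict[str, Any] = field(default_factory=dict)

    def __getitem__(self, key: str) -> np.ndarray:
        return self.maps[key]


# ---------------------------------------------------------------------------
# Model evaluation
# ---------------------------------------------------------------------------


def _eval_model(model: DecayModelSpec, theta: np.ndarray, t: np.ndarray) -> np.ndarray:
    if model.name == "monoexp":
        a, tau, b = theta
        return a * np.exp(-t / tau) + b
    if model.name == "biexp":
        a1, t1, a2, t2, b = theta
        return a1 * np.exp(-t / t1) + a2 * np.exp(-t / t2) + b
    if model.name == "strexp":
        a, tau, h, b = theta
        return a * np.exp(-((t / tau) ** h)) + b
    raise ValueError(f"unknown model {model.name!r}")


def _jac_model(model: DecayModelSpec, theta: np.ndarray, t: np.ndarray) -> np.ndarray:
    if model.name == "monoexp":
        a, tau, _ = theta
        e = np.exp(-t / tau)
        return np.stack([e, a * e * t / tau**2, np.ones_like(t)], axis=1)
    if model.name == "biexp":
        a1, t1, a2, t2, _ = theta
        e1 = np.exp(-t / t1)
        e2 = np.exp(-t / t2)
        return np.stack(
            [e1, a1 * e1 * t / t1**2, e2, a2 * e2 * t / t2**2, np.ones_like(t)], axis=1
        )
    if model.name == "strexp":
        a, tau, h, _ = theta
        with np.errstate(divide="ignore", invalid="ignore"):
            u = (t / tau) ** h
            e = np.exp(-u)
            d_tau = a * e * h * u / tau
            logr = np.where(t > 0, np.log(np.maximum(t, _TAU_MIN) / tau), 0.0)
            d_h = -a * e * u * logr
        return np.stack([e, d_tau, d_h, np.ones_like(t)], axis=1)
    raise ValueError(f"unknown model {model.name!r}")


def _bounds(model: DecayModelSpec) -> tuple[np.ndarray, np.ndarray]:
    lo = {"monoexp": [0.0, _TAU_MIN, 0.0],
          "biexp": [0.0, _TAU_MIN, 0.0, _TAU_MIN, 0.0],
          "strexp": [0.0, _TAU_MIN, 1e-3, 0.0]}[model.name]
    hi = {"monoexp": [np.inf, np.inf, np.inf],
          "biexp": [np.inf, np.inf, np.inf, np.inf, np.inf],
          "strexp": [np.inf, np.inf, _H_MAX, np.inf]}[model.name]
    return np.array(lo), np.array(hi)


def _initial_guess(model: DecayModelSpec, trace: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Deterministic starting point: B from the trace tail, A from the first
    frame, tau from a log-linear regression on background-subtracted early
    frames, h = 1."""
    n = len(trace)
    n_tail = max(1, int(round(0.05 * n)))
    b0 = float(np.mean(trace[-n_tail:]))
    a0 = max(float(trace[0]) - b0, 1e-6 * max(b0, 1.0))

    span = t[-1] - t[0] if t[-1] > t[0] else 1.0
    tau0 = span / 3.0
    bsub = trace - b0
    pos = bsub > max(1e-12, 0.02 * a0)
    pos[n // 2 :] = False  # early frames only
    if np.count_nonzero(pos) >= 3:
        slope = np.polyfit(t[pos], np.log(bsub[pos]), 1)[0]
        if slope < 0:
            tau0 = float(np.clip(-1.0 / slope, 1e-6 * span, 100.0 * span))

    if model.name == "monoexp":
        return np.array([a0, tau0, b0])
    if model.name == "biexp":
        return np.array([a0 / 2.0, tau0 / 3.0, a0 / 2.0, tau0 * 3.0, b0])
    if model.name == "strexp":
        return np.array([a0, tau0, 1.0, b0])
    raise ValueError(f"unknown model {model.name!r}")


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def fit_pixel(
    trace,
    t,
    model: DecayModelSpec | str = MONOEXP,
    options: FitOptions = FitOptions(),
) -> DecayFit:
    """Fit one decay model to a single pixel trace.

    Bounded trust-region least squares (A >= 0, tau > 0, B >= 0,
    0 < h <= 3) with a fixed, data-derived initialization — no randomness.
    Degenerate traces (constant or all-zero) are returned unconverged with
    A = 0 and B = mean(trace).  Bi-exponential components are reported with
    tau1 <= tau2; fits whose time constants are closer than
    ``options.tau_ratio_floor`` are flagged ``effectively_monoexp``.
    """
    if isinstance(model, str):
        model = MODELS[model]
    trace = np.asarray(trace, dtype=float)
    t = np.asarray(t, dtype=float)
    if trace.shape != t.shape or trace.ndim != 1:
        raise ValueError("trace and t must be 1-D arrays of equal length")
    if len(trace) < model.n_params + 1:
        raise ValueError(
            f"need at least {model.n_params + 1} frames to fit {model.name}"
        )

    if np.ptp(trace) == 0.0:
        params = dict.fromkeys(model.param_names, 0.0)
        for key in ("tau", "tau1", "tau2"):
            if key in params:
                params[key] = np.nan
        if "h" in params:
            params["h"] = np.nan
        params["background"] = float(trace.mean())
        return DecayFit(model.name, params, 0.0, 0.0, False, 0, degenerate=True)

    theta0 = _initial_guess(model, trace, t)
    lo, hi = _bounds(model)
    theta0 = np.clip(theta0, lo + 1e-15, None)

    res = least_squares(
        lambda th: _eval_model(model, th, t) - trace,
        theta0,
        jac=lambda th: _jac_model(model, th, t),
        bounds=(lo, hi),
        method="trf",
        xtol=options.xtol,
        max_nfev=options.max_iter,
    )
    theta = res.x
    flags: list[str] = []
    if model.name == "biexp":
        a1, t1, a2, t2, b = theta
        if t1 > t2:
            theta = np.array([a2, t2, a1, t1, b])
        if theta[1] > 0 and theta[3] / theta[1] < options.tau_ratio_floor:
            flags.append("effectively_monoexp")
    resid = _eval_model(model, theta, t) - trace
    chi2 = float(resid @ resid)
    rmse = float(np.sqrt(chi2 / len(trace)))
    converged = bool(res.status > 0)
    return DecayFit(
        model.name,
        dict(zip(model.param_names, (float(v) for v in theta))),
        rmse,
        chi2,
        converged,
        int(res.nfev),
        flags=tuple(flags),
    )


def _fit_mask(stack: BleachStack, options: FitOptions) -> np.ndarray:
    first = stack.data[0]
    if options.min_intensity is not None:
        thr = options.min_intensity
    else:
        thr = np.quantile(first, options.mask_quantile)
    mask = first >= thr
    if not mask.any():
        raise ValueError("intensity mask excludes every pixel")
    return mask


def fit_stack(
    stack: BleachStack,
    model: DecayModelSpec | str = MONOEXP,
    options: FitOptions = FitOptions(),
) -> ParameterMaps:
    """Fit every unmasked pixel of a bleach stack; assemble parameter maps.

    Pixels whose first-frame intensity falls below the mask threshold are
    skipped and carry NaN in all maps.  Per-pixel optimizer failures are
    recorded in the convergence mask and never abort the run.
    """
    if isinstance(model, str):
        model = MODELS[model]
    mask = _fit_mask(stack, options)
    t = stack.times
    ny, nx = stack.spatial_shape

    maps = {name: np.full((ny, nx), np.nan) for name in model.param_names}
    rmse = np.full((ny, nx), np.nan)
    chi2 = np.full((ny, nx), np.nan)
    converged = np.zeros((ny, nx), dtype=bool)

    data = np.ascontiguousarray(stack.data.reshape(stack.n_frames, -1).T)
    rows_logged = max(1, ny // 8)
    for y in range(ny):
        if y % rows_logged == 0:
            logger.info("fit_stack: row %d/%d", y, ny)
        for x in range(nx):
            if not mask[y, x]:
                continue
            fit = fit_pixel(data[y * nx + x], t, model, options)
            for name in model.param_names:
                maps[name][y, x] = fit.params[name]
            rmse[y, x] = fit.rmse
            chi2[y, x] = fit.chi2
            converged[y, x] = fit.converged
    return ParameterMaps(
        model=model.name,
        maps=maps,
        rmse=rmse,
        chi2=chi2,
        converged=converged,
        mask=mask,
        metadata={"dt": stack.dt, "t0": stack.t0, "n_frames": stack.n_frames,
                  "options": options.__dict__.copy()},
    )


# ---------------------------------------------------------------------------
# TiEm images
# ---------------------------------------------------------------------------


def _reconstruct_frames(maps: ParameterMaps, t: np.ndarray, with_background: bool) -> np.ndarray:
    """Model frames (T x Y x X) from fitted maps; NaN where unfitted."""
    m = maps.maps
    tt = t[:, None, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        if maps.model == "monoexp":
            decay = np.where(
                m["amplitude"][None] > 0,
                m["amplitude"][None] * np.exp(-tt / m["tau"][None]),
                0.0,
            )
        elif maps.model == "biexp":
            decay = np.where(
                m["amplitude1"][None] > 0,
                m["amplitude1"][None] * np.exp(-tt / m["tau1"][None]),
                0.0,
            ) + np.where(
                m["amplitude2"][None] > 0,
                m["amplitude2"][None] * np.exp(-tt / m["tau2"][None]),
                0.0,
            )
        elif maps.model == "strexp":
            decay = np.where(
                m["amplitude"][None] > 0,
                m["amplitude"][None]
                * np.exp(-((tt / m["tau"][None]) ** m["h"][None])),
                0.0,
            )
        else:
            raise ValueError(f"unknown model {maps.model!r}")
    decay = np.where(maps.mask[None], decay, np.nan)
    if with_background:
        decay = decay + m["background"][None]
    return decay


def _formula_tiem(maps: ParameterMaps) -> np.ndarray:
    m = maps.maps
    with np.errstate(invalid="ignore"):
        if maps.model == "monoexp":
            out = np.where(m["amplitude"] > 0, m["amplitude"] * m["tau"], 0.0)
        elif maps.model == "biexp":
            out = np.where(m["amplitude1"] > 0, m["amplitude1"] * m["tau1"], 0.0) + np.where(
                m["amplitude2"] > 0, m["amplitude2"] * m["tau2"], 0.0
            )
        elif maps.model == "strexp":
            out = np.where(
                m["amplitude"] > 0,
                m["amplitude"] * m["tau"] * gamma_fn(1.0 + 1.0 / m["h"]),
                0.0,
            )
        else:
            raise ValueError(f"unknown model {maps.model!r}")
    return np.where(maps.mask, out, np.nan)


def tiem_maps(
    maps: ParameterMaps,
    stack: BleachStack,
    mode: str = "formula",
    weighted: bool = True,
) -> np.ndarray:
    """Time-integrated emission image in one of three modes.

    ``formula`` evaluates the closed-form integral of the fitted decay
    (A*tau for mono-exponential — exactly the background-free TiEm);
    ``sum_minus_background`` / ``sum_plus_background`` sum the reconstructed
    model frames over the acquisition, excluding/including the fitted B.
    With ``weighted=True`` (default) the sums carry a factor dt so they have
    the same intensity*s units as the formula mode; ``weighted=False``
    reproduces a plain summed-pixel-intensity image.
    """
    if maps.rmse.shape != stack.spatial_shape:
        raise ValueError("maps and stack are not spatially congruent")
    if mode == "formula":
        return _formula_tiem(maps)
    if mode in ("sum_minus_background", "sum_plus_background"):
        frames = _reconstruct_frames(maps, stack.times, mode == "sum_plus_background")
        out = frames.sum(axis=0)
        return out * stack.dt if weighted else out
    raise ValueError(f"unknown TiEm mode {mode!r}")


def cumulative_integral_stack(
    maps: ParameterMaps,
    t_grid: np.ndarray,
    with_background: bool = False,
    dt: float | None = None,
) -> np.ndarray:
    """Integrated model signal as a function of acquisition number.

    Frame n is the dt-weighted sum of the reconstructed model frames 0..n —
    the spatial version of the finite-time bleach integral; per pixel it is
    monotone non-decreasing and, without background, converges to the
    ``sum_minus_background`` TiEm image.  Including the background adds a
    linear-in-time term B*t that grows without bound.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if dt is None:
        dt = float(t_grid[1] - t_grid[0]) if len(t_grid) > 1 else 1.0
    frames = _reconstruct_frames(maps, t_grid, with_background)
    return np.cumsum(frames, axis=0) * dt


# ---------------------------------------------------------------------------
# Model selection
# ---------------------------------------------------------------------------


def _aicc(chi2: float, n: int, k: int, rss_floor: float = 1e-300) -> float:
    # the floor ties "perfect" fits to the numerical precision of the data
    # scale, so near-zero residuals compare as ties instead of amplifying
    # floating-point noise through log(RSS)
    rss = max(chi2, rss_floor)
    pen = 2.0 * k + (2.0 * k * (k + 1.0)) / max(n - k - 1.0, 1.0)
    return n * np.log(rss / n) + pen


def select_model(
    stack: BleachStack,
    candidates: Sequence[DecayModelSpec | str] = (MONOEXP, STREXP),
    options: FitOptions = FitOptions(),
) -> tuple[np.ndarray, dict[str, ParameterMaps], np.ndarray]:
    """Per-pixel model choice by corrected Akaike information criterion.

    Fits every candidate model to every unmasked pixel, scores the residual
    sum of squares with AICc, and returns ``(labels, fits, margin)`` where
    ``labels`` holds the winning model name per pixel ('' where masked),
    ``fits`` maps model name to its ParameterMaps and ``margin`` is the AICc
    gap to the runner-up.  Candidates are ranked simplest-first, and a
    candidate only wins with a strictly better score — on perfect ties the
    model with fewest parameters is kept.
    """
    models = [MODELS[c] if isinstance(c, str) else c for c in candidates]
    if len(models) < 2:
        raise ValueError("need at least two candidate models")
    models = sorted(models, key=lambda mdl: mdl.n_params)
    fits = {mdl.name: fit_stack(stack, mdl, options) for mdl in models}

    n = stack.n_frames
    ny, nx = stack.spatial_shape
    labels = np.full((ny, nx), "", dtype=object)
    margin = np.full((ny, nx), np.nan)
    mask = fits[models[0].name].mask
    scores = np.full((len(models), ny, nx), np.inf)
    for i, mdl in enumerate(models):
        pm = fits[mdl.name]
        with np.errstate(invalid="ignore"):
            valid = mask & np.isfinite(pm.chi2)
        sc = np.full((ny, nx), np.inf)
        ys, xs = np.nonzero(valid)
        first = stack.data[0]
        for y, x in zip(ys, xs):
            floor = n * (1e-8 * max(float(first[y, x]), 1.0)) ** 2
            sc[y, x] = _aicc(pm.chi2[y, x], n, mdl.n_params, floor)
        scores[i] = sc

    best = np.zeros((ny, nx), dtype=int)
    for i in range(1, len(models)):
        better = scores[i] < scores[best, np.arange(ny)[:, None], np.arange(nx)[None, :]] - 1e-9
        best = np.where(better, i, best)
    for i, mdl in enumerate(models):
        labels[(best == i) & mask] = mdl.name
    sorted_scores = np.sort(scores, axis=0)
    margin = np.where(mask, sorted_scores[1] - sorted_scores[0], np.nan)
    return labels, fits, margin


# ---------------------------------------------------------------------------
# Region statistics
# ---------------------------------------------------------------------------


def region_statistics(
    maps: ParameterMaps, labels: np.ndarray, names: dict[int, str] | None = None
):
    """Per-region mean/std of every fitted map as a pandas DataFrame."""
    import pandas as pd

    rows = []
    for lab in np.unique(labels):
        sel = (labels == lab) & maps.mask
        if not sel.any():
            continue
        row: dict[str, Any] = {
            "label": int(lab),
            "region": (names or {}).get(int(lab), str(int(lab))),
            "n_pixels": int(sel.sum()),
        }
        for name, arr in {**maps.maps, "rmse": maps.rmse}.items():
            vals = arr[sel]
            vals = vals[np.isfinite(vals)]
            row[f"{name}_mean"] = float(vals.mean()) if vals.size else np.nan
            row[f"{name}_std"] = float(vals.std()) if vals.size else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
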