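"""Synthetic bleach-stack generator for validating pixel-wise decay fitting.

The generated scene emulates a wide-field bleach experiment with two known
artefacts built in:

* illumination shading, modelled as a row-wise linear ramp of the photocycle
  equilibrium constant q (photons/molecule) across the field of view;
* compartment-specific autofluorescence, modelled as a two-compartment cell
  phantom — a nucleus with a high fluorophore amount on a low constant
  background inside a cytoplasm with a lower amount on a high background.

Per pixel, the intensity decays as the rapid-equilibrium singlet bleaching
model M*q/(1+q)*exp(-k2*q/(1+q)*t) plus the constant background B.  The
intrinsic bleach rate constant k2 is perturbed once per pixel by zero-mean
Gaussian noise produced with the Box–Muller transform, freezing a slightly
different bleach behaviour into every pixel.  Ground-truth parameter maps are
returned with each rendered stack so fits can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .photokinetics import PhotocycleParams, SingletBleachParams, singlet_bleach_decay
from .pixelfit import BleachStack

__all__ = [
    "SynthSpec",
    "make_qmap",
    "make_cell_phantom",
    "box_muller",
    "gaussian_field",
    "make_k2map",
    "render_stack",
    "render_strexp_stack",
    "default_spec",
]

#: k2 values from the Gaussian tail are clipped here; the TiEm M/k2 diverges
#: at k2 = 0, so truly non-bleaching pixels are excluded by construction.
K2_FLOOR = 1e-6

LABEL_OUTSIDE, LABEL_CYTOPLASM, LABEL_NUCLEUS = 0, 1, 2


@dataclass
class SynthSpec:
    """Complete, reproducible recipe for one synthetic bleach stack.

    Defaults reproduce the validation scene: a 256x256 field with q ramping
    row-wise from 8.0 (bottom) to 2.0 (top) photons/molecule, a nucleus with
    M = 7000 molecules on background 100 inside a cytoplasm with M = 5000 on
    background 600, k2 = 0.1 s^-1 perturbed per pixel by 0.01*N(0, 1), and
    100 frames at 1 s intervals.
    """

    shape: tuple[int, int] = (256, 256)
    q_bottom: float = 8.0
    q_top: float = 2.0
    m_nucleus: float = 7000.0
    m_cytoplasm: float = 5000.0
    b_nucleus: float = 100.0
    b_cytoplasm: float = 600.0
    k2_base: float = 0.1
    noise_amp: float = 0.01
    noise_var: float = 1.0
    n_frames: int = 100
    dt: float = 1.0
    seed: int = 0
    read_noise_sd: float = 0.0
    nucleus_axes: tuple[float, float] | None = None
    cyto_axes: tuple[float, float] | None = None

    def to_dict(self) -> dict[str, Any]:
        d = dict(self.__dict__)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SynthSpec":
        kw = dict(d)
        for k in ("shape", "nucleus_axes", "cyto_axes"):
            if kw.get(k) is not None:
                kw[k] = tuple(kw[k])
        return cls(**kw)


def make_qmap(shape: tuple[int, int], q_bottom: float = 8.0, q_top: float = 2.0) -> np.ndarray:
    """Row-wise linear ramp of q from ``q_top`` (row 0) to ``q_bottom`` (last row).

    Image row 0 is displayed at the top, so the bottom of the field carries
    ``q_bottom``.  Each row is constant, mimicking line-wise illumination
    shading.
    """
    if q_bottom <= 0 or q_top <= 0:
        raise ValueError("q values must be positive")
    ny, nx = shape
    if ny < 1 or nx < 1:
        raise ValueError("shape must be positive")
    rows = np.linspace(q_top, q_bottom, ny) if ny > 1 else np.array([(q_top + q_bottom) / 2.0])
    return np.repeat(rows[:, None], nx, axis=1)


def _ellipse_mask(shape: tuple[int, int], center: tuple[float, float], axes: tuple[float, float]) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    cy, cx = center
    ay, ax = axes
    if ay == 0 or ax == 0:
        return np.zeros(shape, dtype=bool)
    return ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def make_cell_phantom(
    shape: tuple[int, int] = (256, 256),
    m_nucleus: float = 7000.0,
    m_cytoplasm: float = 5000.0,
    b_nucleus: float = 100.0,
    b_cytoplasm: float = 600.0,
    nucleus_axes: tuple[float, float] | None = None,
    cyto_axes: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two-compartment cell phantom: concentric ellipses.

    Returns ``(M_map, B_map, labels)`` where labels are 0 outside the cell,
    1 in the cytoplasm and 2 in the nucleus.  Defaults put M = 7000 molecules
    on background 100 in the nucleus and M = 5000 on background 600 in the
    cytoplasm; outside the cell both maps are zero.
    """
    ny, nx = shape
    center = ((ny - 1) / 2.0, (nx - 1) / 2.0)
    if cyto_axes is None:
        cyto_axes = (0.42 * ny, 0.42 * nx)
    if nucleus_axes is None:
        nucleus_axes = (0.16 * ny, 0.16 * nx)
    if nucleus_axes[0] > cyto_axes[0] or nucleus_axes[1] > cyto_axes[1]:
        raise ValueError("nucleus must lie inside the cytoplasm")
    if cyto_axes[0] > ny / 2.0 or cyto_axes[1] > nx / 2.0:
        raise ValueError("cell must lie inside the frame")

    cyto = _ellipse_mask(shape, center, cyto_axes)
    nuc = _ellipse_mask(shape, center, nucleus_axes)

    labels = np.zeros(shape, dtype=np.uint8)
    labels[cyto] = LABEL_CYTOPLASM
    labels[nuc] = LABEL_NUCLEUS

    m_map = np.zeros(shape, dtype=float)
    b_map = np.zeros(shape, dtype=float)
    m_map[labels == LABEL_CYTOPLASM] = m_cytoplasm
    b_map[labels == LABEL_CYTOPLASM] = b_cytoplasm
    m_map[labels == LABEL_NUCLEUS] = m_nucleus
    b_map[labels == LABEL_NUCLEUS] = b_nucleus
    return m_map, b_map, labels


def box_muller(u1, u2):
    """Box–Muller transform: standard-normal deviate from two uniforms.

    z = sqrt(-2*ln(u1)) * cos(2*pi*u2), with u1 in (0, 1] and u2 in [0, 1).
    Implemented explicitly (rather than through a library normal generator)
    because the per-pixel bleach-rate perturbation is defined in terms of
    this transform.
    """
    u1 = np.asarray(u1, dtype=float)
    u2 = np.asarray(u2, dtype=float)
    if np.any(u1 <= 0) or np.any(u1 > 1):
        raise ValueError("u1 must lie in (0, 1]")
    if np.any(u2 < 0) or np.any(u2 >= 1):
        raise ValueError("u2 must lie in [0, 1)")
    out = np.sqrt(-2.0 * np.log(u1)) * np.cos(2.0 * np.pi * u2)
    return out if out.ndim else float(out)


def gaussian_field(shape: tuple[int, int], seed: int) -> np.ndarray:
    """Standard-normal field drawn via Box–Muller from seeded uniforms."""
    rng = np.random.default_rng(seed)
    # u1 in (0, 1]: flip the half-open [0, 1) interval
    u1 = 1.0 - rng.random(shape)
    u2 = rng.random(shape)
    return box_muller(u1, u2)


def make_k2map(
    shape: tuple[int, int],
    k2_base: float = 0.1,
    noise_amp: float = 0.01,
    noise_var: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Per-pixel intrinsic bleach rate constants (s^-1).

    k2(x, y) = k2_base + noise_amp * N(0, noise_var), drawn once per pixel
    (Box–Muller) and frozen for the whole stack; clipped below at
    ``K2_FLOOR`` so no pixel is exactly non-bleaching.
    """
    if k2_base <= 0:
        raise ValueError("k2_base must be > 0")
    if noise_amp < 0:
        raise ValueError("noise_amp must be >= 0")
    z = gaussian_field(shape, seed) * np.sqrt(noise_var)
    return np.clip(k2_base + noise_amp * z, K2_FLOOR, None)


def _ground_truth(q_map, m_map, b_map, k2_map):
    qf = q_map / (1.0 + q_map)
    amp = m_map * qf
    kb = k2_map * qf
    with np.errstate(divide="ignore"):
        tau = np.where(kb > 0, 1.0 / kb, np.inf)
    return {"amplitude": amp, "tau": tau, "background": b_map, "k2": k2_map, "q": q_map, "M": m_map}


def render_stack(spec: SynthSpec) -> tuple[BleachStack, dict[str, np.ndarray]]:
    """Render the bleach stack defined by ``spec`` plus ground-truth maps.

    Frame i at pixel (y, x):

        I = M*qf*exp(-k2*qf*t_i) + B  (+ optional Gaussian read noise)

    with qf = q/(1+q) from the shading ramp and t_i = i*dt.  Outside the cell
    (M = B = 0) the noise-free signal is identically zero.  Ground truth
    contains the amplitude, observed time constant, background, k2, q and M
    maps.
    """
    q_map = make_qmap(spec.shape, spec.q_bottom, spec.q_top)
    m_map, b_map, labels = make_cell_phantom(
        spec.shape,
        spec.m_nucleus,
        spec.m_cytoplasm,
        spec.b_nucleus,
        spec.b_cytoplasm,
        spec.nucleus_axes,
        spec.cyto_axes,
    )
    k2_map = make_k2map(spec.shape, spec.k2_base, spec.noise_amp, spec.noise_var, spec.seed)

    t = np.arange(spec.n_frames) * spec.dt
    qf = q_map / (1.0 + q_map)
    amp = m_map * qf
    kb = k2_map * qf
    data = amp[None] * np.exp(-kb[None] * t[:, None, None]) + b_map[None]
    if spec.read_noise_sd > 0:
        rng = np.random.default_rng(spec.seed + 1)
        data = data + rng.normal(0.0, spec.read_noise_sd, data.shape)
        data = np.clip(data, 0.0, None)
    truth = _ground_truth(q_map, m_map, b_map, k2_map)
    truth["labels"] = labels
    return BleachStack(data=data, dt=spec.dt), truth


def render_strexp_stack(
    spec: SynthSpec,
    h_nucleus: float = 1.45,
    h_cytoplasm: float = 1.1,
) -> tuple[BleachStack, dict[str, np.ndarray]]:
    """Render a stack whose compartments decay by stretched exponentials.

    The nucleus compartment stands in for "droplet-like" regions with a
    strongly stretched decay (default h = 1.45) while the cytoplasm bleaches
    near-mono-exponentially (default h = 1.1); h = 1 everywhere reproduces
    :func:`render_stack` exactly.  Per-pixel tau is 1/(k2*qf) as in the
    mono-exponential scene.
    """
    if h_nucleus <= 0 or h_cytoplasm <= 0:
        raise ValueError("stretching parameters must be > 0")
    q_map = make_qmap(spec.shape, spec.q_bottom, spec.q_top)
    m_map, b_map, labels = make_cell_phantom(
        spec.shape,
        spec.m_nucleus,
        spec.m_cytoplasm,
        spec.b_nucleus,
        spec.b_cytoplasm,
        spec.nucleus_axes,
        spec.cyto_axes,
    )
    k2_map = make_k2map(spec.shape, spec.k2_base, spec.noise_amp, spec.noise_var, spec.seed)

    h_map = np.ones(spec.shape, dtype=float)
    h_map[labels == LABEL_CYTOPLASM] = h_cytoplasm
    h_map[labels == LABEL_NUCLEUS] = h_nucleus

    t = np.arange(spec.n_frames) * spec.dt
    qf = q_map / (1.0 + q_map)
    amp = m_map * qf
    kb = k2_map * qf
    with np.errstate(divide="ignore"):
        tau = np.where(kb > 0, 1.0 / kb, np.inf)
    ratio = np.where(np.isfinite(tau), t[:, None, None] / tau[None], 0.0)
    data = amp[None] * np.exp(-(ratio ** h_map[None])) + b_map[None]
    if spec.read_noise_sd > 0:
        rng = np.random.default_rng(spec.seed + 1)
        data = data + rng.normal(0.0, spec.read_noise_sd, data.shape)
        data = np.clip(data, 0.0, None)
    truth = _ground_truth(q_map, m_map, b_map, k2_map)
    truth["labels"] = labels
    truth["h"] = h_map
    return BleachStack(data=data, dt=spec.dt), truth


def default_spec(**overrides) -> SynthSpec:
    """The standard shading-phantom recipe, with optional field overrides."""
    return SynthSpec(**overrides)
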