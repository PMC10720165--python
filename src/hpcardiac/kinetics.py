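"""Uni-directional three-site pharmacokinetic model for hyperpolarized pyruvate.

Hyperpolarized [1-13C]-pyruvate magnetization is non-renewable: each
excitation consumes a ``cos(theta)`` fraction and T1 relaxation destroys the
remainder on a ~30 s timescale.  Conversion to [1-13C]-lactate (via LDH, rate
``k_PL``) and 13C-bicarbonate (via PDH, rate ``k_PB``) is modeled as
uni-directional first-order exchange in a single physical compartment:

    dM_L/dt = -M_L/T1_L + k_PL * M_P(t)
    dM_B/dt = -M_B/T1_B + k_PB * M_P(t)

Dynamic multi-slice imaging samples each metabolite once per slice per frame,
so the discrete model advances frame-to-frame: at each frame the transverse
signal is ``S_X = M_X * sin(theta_X)``, the excitation leaves
``M_X * cos(theta_X)`` longitudinal, and between frames the magnetization
relaxes while accumulating converted pyruvate.  The pyruvate magnetization is
interpolated mono-exponentially between its frame endpoints, which makes the
product-pool convolution integral closed-form.

The "inputless" fitting strategy uses the *measured* pyruvate signal itself as
the precursor input, so no arterial-input-function model is assumed; with
fixed T1s the only free parameters are the two rates, left unbounded so that
zero-mean noise can produce small negative estimates without bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares


@dataclass(frozen=True)
class RelaxationTimes:
    """Fixed longitudinal relaxation times (s) of the three 13C pools."""

    t1_pyruvate: float = 30.0
    t1_lactate: float = 25.0
    t1_bicarbonate: float = 20.0

    def __post_init__(self) -> None:
        for name in ("t1_pyruvate", "t1_lactate", "t1_bicarbonate"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class FlipSchedule:
    """Excitation flip angles (degrees) and frame times (s).

    One excitation per metabolite per slice per frame (2D multislice), so a
    single ``cos(theta)`` loss is applied per frame.
    """

    times: np.ndarray
    theta_pyruvate: float = 20.0
    theta_lactate: float = 30.0
    theta_bicarbonate: float = 30.0

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        if times.ndim != 1 or times.size < 1:
            raise ValueError("times must be a 1-D array with at least one frame")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("frame times must be strictly increasing")
        object.__setattr__(self, "times", times)
        for name in ("theta_pyruvate", "theta_lactate", "theta_bicarbonate"):
            theta = getattr(self, name)
            if not 0 < theta < 90:
                raise ValueError(f"{name} must lie in (0, 90) degrees")

    @property
    def n_frames(self) -> int:
        return self.times.size


@dataclass
class MetaboliteTimecourses:
    """Per-frame real-valued transverse signals (and model magnetizations)."""

    s_pyruvate: np.ndarray
    s_lactate: np.ndarray
    s_bicarbonate: np.ndarray
    m_pyruvate: np.ndarray | None = None
    m_lactate: np.ndarray | None = None
    m_bicarbonate: np.ndarray | None = None


@dataclass
class FitResult:
    """Outcome of an inputless rate fit."""

    k_pl: float
    k_pb: float
    rss: float
    s_lactate_fit: np.ndarray
    s_bicarbonate_fit: np.ndarray
    converged: bool
    message: str = ""


def _interval_conversion(p_start, p_end, dt, t1x):
    """Closed-form integral of interpolated pyruvate against product decay.

    Computes ``C = int_0^dt P(tau) exp(-(dt - tau)/t1x) dtau`` where ``P`` is
    mono-exponential between ``p_start`` and ``p_end``; flat at ``p_start``
    when either endpoint is non-positive (the mono-exponential is undefined
    there, and signed noise must pass through unrectified).

    Vectorized over voxels: ``p_start``/``p_end`` may be arrays.
    """
    p_start = np.asarray(p_start, dtype=float)
    p_end = np.asarray(p_end, dtype=float)
    rate = np.zeros(np.broadcast(p_start, p_end).shape)
    ok = (p_start > 0) & (p_end > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(ok, np.log(np.where(ok, p_end, 1.0) /
                                   np.where(ok, p_start, 1.0)) / dt, 0.0)
    a = rate + 1.0 / t1x
    # C = p_start * exp(-dt/t1x) * (exp(a*dt) - 1) / a, stable via expm1
    small = np.abs(a * dt) < 1e-12
    frac = np.where(small, dt, np.expm1(np.where(small, 0.0, a) * dt) /
                    np.where(small, 1.0, a))
    return p_start * np.exp(-dt / t1x) * frac


def _product_recursion(p_post, p_pre, times, k_px, t1x, cos_x, m_x0):
    """Advance one product pool through the frame recursion.

    ``p_post[i]`` is the pyruvate magnetization just after the excitation of
    frame ``i``; ``p_pre[i+1]`` just before frame ``i+1``.  Returns the
    pre-excitation product magnetization at every frame.  Vectorized over a
    trailing voxel axis.
    """
    n = len(times)
    m = np.empty((n,) + np.shape(m_x0))
    m[0] = m_x0
    for i in range(n - 1):
        dt = times[i + 1] - times[i]
        c = _interval_conversion(p_post[i], p_pre[i + 1], dt, t1x)
        m[i + 1] = m[i] * cos_x * np.exp(-dt / t1x) + k_px * c
    return m


def forward_model(
    aif,
    k_pl: float,
    k_pb: float,
    relax: RelaxationTimes,
    flips: FlipSchedule,
    m_p0: float = 0.0,
    m_l0: float = 0.0,
    m_b0: float = 0.0,
    n_quad: int = 64,
) -> MetaboliteTimecourses:
    """Simulate the three-pool frame recursion driven by an input function.

    Parameters
    ----------
    aif : callable or None
        Pyruvate delivery rate (magnetization units / s) as a function of
        time; ``None`` means no input (decay of ``m_p0`` only).
    k_pl, k_pb : float
        Apparent conversion rates (1/s).  Pyruvate is depleted by both.
    m_p0, m_l0, m_b0 : float
        Pre-excitation longitudinal magnetizations at the first frame.

    The pyruvate delivery integral per frame interval is evaluated with
    Gauss-Legendre quadrature (exact model, no discretization of the AIF);
    the product pools use the closed-form recursion, with pyruvate
    interpolated mono-exponentially between its frame endpoints.
    """
    times = flips.times
    n = times.size
    rho = 1.0 / relax.t1_pyruvate + k_pl + k_pb  # pyruvate loss rate
    cos_p = np.cos(np.deg2rad(flips.theta_pyruvate))

    p_pre = np.empty(n)
    p_post = np.empty(n)
    p_pre[0] = m_p0
    gl_x, gl_w = np.polynomial.legendre.leggauss(n_quad)
    for i in range(n - 1):
        p_post[i] = p_pre[i] * cos_p
        dt = times[i + 1] - times[i]
        decayed = p_post[i] * np.exp(-rho * dt)
        if aif is not None:
            # map Gauss-Legendre nodes onto [t_i, t_{i+1}]
            t_nodes = times[i] + 0.5 * dt * (gl_x + 1.0)
            vals = np.asarray(aif(t_nodes), dtype=float)
            delivered = 0.5 * dt * np.sum(
                gl_w * vals * np.exp(-rho * (times[i + 1] - t_nodes))
            )
        else:
            delivered = 0.0
        p_pre[i + 1] = decayed + delivered
    p_post[-1] = p_pre[-1] * cos_p

    cos_l = np.cos(np.deg2rad(flips.theta_lactate))
    cos_b = np.cos(np.deg2rad(flips.theta_bicarbonate))
    m_l = _product_recursion(p_post, p_pre, times, k_pl,
                             relax.t1_lactate, cos_l, float(m_l0))
    m_b = _product_recursion(p_post, p_pre, times, k_pb,
                             relax.t1_bicarbonate, cos_b, float(m_b0))

    return MetaboliteTimecourses(
        s_pyruvate=p_pre * np.sin(np.deg2rad(flips.theta_pyruvate)),
        s_lactate=m_l * np.sin(np.deg2rad(flips.theta_lactate)),
        s_bicarbonate=m_b * np.sin(np.deg2rad(flips.theta_bicarbonate)),
        m_pyruvate=p_pre,
        m_lactate=m_l,
        m_bicarbonate=m_b,
    )


def predict_inputless(
    s_pyruvate: np.ndarray,
    k_pl,
    k_pb,
    relax: RelaxationTimes,
    flips: FlipSchedule,
    m_l0=0.0,
    m_b0=0.0,
):
    """Predict lactate/bicarbonate signals from the measured pyruvate signal.

    The measured pyruvate signal defines the precursor magnetization directly
    (``M_P(i-) = S_P(i)/sin(theta_P)``), so no analytic input function is
    assumed.  Accepts a trailing voxel axis on ``s_pyruvate`` (shape
    ``(n_frames,)`` or ``(n_frames, n_vox)``) with matching ``k_pl``/``k_pb``
    scalars or per-voxel arrays.

    Returns ``(s_lactate, s_bicarbonate)`` with the same shape as input.
    """
    s_p = np.asarray(s_pyruvate, dtype=float)
    if s_p.shape[0] != flips.n_frames:
        raise ValueError("s_pyruvate length does not match the flip schedule")
    sin_p = np.sin(np.deg2rad(flips.theta_pyruvate))
    cos_p = np.cos(np.deg2rad(flips.theta_pyruvate))
    p_pre = s_p / sin_p
    p_post = p_pre * cos_p

    cos_l = np.cos(np.deg2rad(flips.theta_lactate))
    cos_b = np.cos(np.deg2rad(flips.theta_bicarbonate))
    m_l0 = np.broadcast_to(np.asarray(m_l0, dtype=float), s_p.shape[1:]).copy() \
        if s_p.ndim > 1 else float(np.asarray(m_l0))
    m_b0 = np.broadcast_to(np.asarray(m_b0, dtype=float), s_p.shape[1:]).copy() \
        if s_p.ndim > 1 else float(np.asarray(m_b0))
    m_l = _product_recursion(p_post, p_pre, flips.times, k_pl,
                             relax.t1_lactate, cos_l, m_l0)
    m_b = _product_recursion(p_post, p_pre, flips.times, k_pb,
                             relax.t1_bicarbonate, cos_b, m_b0)
    return (m_l * np.sin(np.deg2rad(flips.theta_lactate)),
            m_b * np.sin(np.deg2rad(flips.theta_bicarbonate)))


def fit_inputless(
    timecourses: MetaboliteTimecourses,
    relax: RelaxationTimes,
    flips: FlipSchedule,
    initial_guess: tuple[float, float] = (0.01, 0.005),
) -> FitResult:
    """Fit (k_PL, k_PB) by unconstrained local least squares.

    Minimizes the summed squared residuals of the lactate and bicarbonate
    signals predicted from the measured pyruvate.  The initial lactate and
    bicarbonate magnetizations are taken from the first measured frame
    (signed, as measured — noise is not rectified).  No bounds are imposed,
    so noise may yield small negative rates.  Non-convergence is flagged on
    the result rather than raised.
    """
    s_p = np.asarray(timecourses.s_pyruvate, dtype=float)
    s_l = np.asarray(timecourses.s_lactate, dtype=float)
    s_b = np.asarray(timecourses.s_bicarbonate, dtype=float)
    if s_p.size < 3:
        raise ValueError("need at least 3 frames to fit two rates")
    m_l0 = s_l[0] / np.sin(np.deg2rad(flips.theta_lactate))
    m_b0 = s_b[0] / np.sin(np.deg2rad(flips.theta_bicarbonate))

    def residuals(k):
        pred_l, pred_b = predict_inputless(s_p, k[0], k[1], relax, flips,
                                           m_l0=m_l0, m_b0=m_b0)
        return np.concatenate([pred_l - s_l, pred_b - s_b])

    sol = least_squares(residuals, x0=np.asarray(initial_guess, dtype=float),
                        method="lm")
    pred_l, pred_b = predict_inputless(s_p, sol.x[0], sol.x[1], relax, flips,
                                       m_l0=m_l0, m_b0=m_b0)
    return FitResult(
        k_pl=float(sol.x[0]),
        k_pb=float(sol.x[1]),
        rss=float(np.sum((pred_l - s_l) ** 2) + np.sum((pred_b - s_b) ** 2)),
        s_lactate_fit=pred_l,
        s_bicarbonate_fit=pred_b,
        converged=bool(sol.status > 0),
        message=sol.message,
    )


def fit_rate_maps(
    images: np.ndarray,
    mask: np.ndarray,
    relax: RelaxationTimes,
    flips: FlipSchedule,
) -> tuple[np.ndarray, np.ndarray]:
    """Voxelwise inputless rate fitting inside a mask.

    Parameters
    ----------
    images : ndarray, shape (3, n_frames, *spatial)
        Real-valued (phased) dynamics, metabolite axis ordered
        (pyruvate, lactate, bicarbonate).
    mask : boolean ndarray, shape spatial
        Voxels to fit; everywhere else the maps hold NaN.

    Returns
    -------
    (k_pl_map, k_pb_map) : float ndarrays shaped like ``mask``, NaN outside.
    """
    images = np.asarray(images, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if images.ndim < 3 or images.shape[0] != 3:
        raise ValueError("images must be (3, n_frames, *spatial)")
    if images.shape[2:] != mask.shape:
        raise ValueError("mask shape does not match image spatial shape")

    k_pl_map = np.full(mask.shape, np.nan)
    k_pb_map = np.full(mask.shape, np.nan)
    if not mask.any():
        import warnings

        warnings.warn("empty mask: rate maps are all-undefined", stacklevel=2)
        return k_pl_map, k_pb_map

    idx = np.argwhere(mask)
    for voxel in idx:
        sel = (slice(None), slice(None)) + tuple(voxel)
        tc = MetaboliteTimecourses(
            s_pyruvate=images[sel][0],
            s_lactate=images[sel][1],
            s_bicarbonate=images[sel][2],
        )
        fit = fit_inputless(tc, relax, flips)
        k_pl_map[tuple(voxel)] = fit.k_pl
        k_pb_map[tuple(voxel)] = fit.k_pb
    return k_pl_map, k_pb_map
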