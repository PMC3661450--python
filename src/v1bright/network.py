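"""Recurrent excitatory/inhibitory cortical dynamics.

Each retinotopic grid position hosts a hypercolumn of excitatory/inhibitory
unit pairs, one pair per (scale, orientation, contrast polarity).  Membrane
potentials follow the coupled rate equations (time in units of the membrane
time constant tau)

    dx/dt = -x - sum_dtheta psi(dtheta) g_y(y) + J0 g_x(x)
            + sum J g_x  + I_drive + I0 + noise
    dy/dt = -y + g_x(x) + sum W g_x + Ic + I_norm

where J is monosynaptic excitation between near-coaligned, similarly
oriented units (bow-tie geometry), W is disynaptic inhibition between
flanking non-aligned units, psi spreads inhibition across orientations
within a hypercolumn, and I_norm is an activity-dependent normalization
current proportional to the squared local mean firing rate.  Lateral
coupling factorizes into a translation-invariant spatial/orientation kernel
times a Gaussian scale-interaction factor Gs(s, s').  ON and OFF polarity
channels evolve as two independent copies of the network.

Integration is first-order forward Euler.  Lateral sums are evaluated as
translation-invariant correlations via FFTs; the "mirror" boundary rule
reflects the activity beyond the image border (virtual mirrored network),
while "wrap" is exactly periodic and is the mode under which translation
equivariance holds to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage
from scipy.fft import next_fast_len, rfft2, irfft2

from .wavelet import RectifiedDrive, N_ORIENT

__all__ = [
    "ModelParams",
    "ConnectivityKernel",
    "NetworkState",
    "StaticResponse",
    "DynamicResponse",
    "g_x",
    "g_y",
    "build_connectivity",
    "CorticalNetwork",
    "step",
    "run_static",
    "run_dynamic",
]

_PI = np.pi


@dataclass
class ModelParams:
    """All tunable constants of the cortical model.

    Times are in membrane time constants unless suffixed ``_ms``; the grid
    unit is one pixel of the (undecimated) wavelet representation.
    """

    tau_ms: float = 10.0          # membrane time constant
    dt: float = 0.1               # Euler step, fraction of tau
    Tx: float = 1.0               # excitatory firing threshold
    Ty: float = 0.0               # inhibitory firing threshold
    gx_sat: float = 1.0           # excitatory saturation rate
    gy_slopes: tuple[float, float] = (0.21, 2.5)
    gy_knee: float = 1.2          # knee of the inhibitory gain (above Ty)
    J0: float = 0.8               # self-excitation
    psi: tuple[float, float, float] = (1.0, 0.8, 0.0)  # dtheta = 0,45,>=90 deg
    I0: float = 0.85              # excitatory background input
    Ic: float = 1.0               # inhibitory background input
    norm_strength: float = 2.0    # divisive-normalization pool gain
    norm_radius: int = 2          # half-width of the spatial pool box
    noise_amp: float = 0.085      # uniform background noise (0.1 * I0)
    seed: int = 0
    avg_window: float = 12.0      # averaging duration, in tau
    settle_time: float = 20.0     # discarded transient, in tau
    sigma_scale: float = 1.0      # width of Gs, octaves
    scale_cutoff: int = 2         # Gs truncated beyond this |s - s'|
    conn_radius: int = 10         # max lateral reach, grid units
    boundary: str = "mirror"      # "mirror" | "wrap"
    # lateral-kernel constants (contour-integration model family)
    j_strength: float = 0.126
    w_strength: float = 0.14
    j_dist_decay: float = 90.0
    j_beta_gate: float = _PI / 2.69
    j_beta_gate_wide: float = _PI / 1.1
    j_theta_gate: float = _PI / 5.9
    w_beta_gate: float = _PI / 1.1
    w_theta_gate: float = _PI / 11.999
    w_dtheta_gate: float = _PI / 3.0
    w_sat: float = 0.4
    w_min_dist: float = 2.5       # inhibition starts beyond the RF radius
    dilation_base: float = 2.0    # lateral reach grows by this per octave
    max_reach_px: int = 48        # hard cap on lateral reach, pixels
    lateral_gain: float = 0.25    # compensates the redundancy of the
                                  # undecimated grid (~footprint of
                                  # units per feature element)
    norm_lo: float = 1.0          # drive normalization bounds
    norm_hi: float = 3.0

    def __post_init__(self) -> None:
        if self.tau_ms <= 0:
            raise ValueError("tau must be positive")
        if not (0.0 < self.dt <= 0.2):
            raise ValueError("dt must lie in (0, 0.2] membrane time constants")
        if self.avg_window < 1:
            raise ValueError("avg_window must be >= 1 tau")
        if self.boundary not in ("mirror", "wrap"):
            raise ValueError("boundary must be 'mirror' or 'wrap'")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ConnectivityKernel:
    """Translation-invariant coupling tables.

    ``J``/``W`` are the base (finest-scale) spatial tables of shape
    (4, 4, K, K) with K = 2*radius + 1, indexed
    [theta_post, theta_pre, drow + radius, dcol + radius]: the weight from a
    presynaptic unit displaced by (drow, dcol) from the postsynaptic one.
    ``Gs`` is the (n_scales, n_scales) scale-interaction factor and ``psi``
    the (4, 4) within-hypercolumn inhibition spread.

    Horizontal connections span distances proportional to receptive-field
    size: the coupling between scales s and s' uses the base table dilated
    by ``pair_dilation[s, s']`` (geometry in scale-grid units, weights
    divided by dilation^2 so that a pattern and its dilated copy receive
    the same lateral input), times ``Gs[s, s']``.  ``j_tables``/``w_tables``
    hold the dilated spatial tables keyed by dilation factor.
    """

    J: np.ndarray
    W: np.ndarray
    Gs: np.ndarray
    psi: np.ndarray
    radius: int
    pair_dilation: np.ndarray | None = None
    j_tables: dict | None = None
    w_tables: dict | None = None

    @property
    def n_scales(self) -> int:
        return self.Gs.shape[0]

    def spatial_kernel(self, s: int, s_pre: int, which: str = "J") -> np.ndarray:
        """Dilated (4, 4, K, K) spatial table for a scale pair (0-based)."""
        tables = self.j_tables if which == "J" else self.w_tables
        return tables[float(self.pair_dilation[s, s_pre])]

    @property
    def max_reach(self) -> int:
        """Largest spatial radius over all scale pairs, in pixels."""
        tables = self.j_tables or {1.0: self.J}
        return max(t.shape[-1] // 2 for t in tables.values())


@dataclass
class NetworkState:
    """Membrane potentials of every unit at one instant.

    ``x`` and ``y`` have shape (2, n_scales, 4, H, W): polarity (ON, OFF)
    x scale x orientation x grid.
    """

    x: np.ndarray
    y: np.ndarray
    t: float = 0.0


def g_x(x: np.ndarray, params: ModelParams) -> np.ndarray:
    """Excitatory firing rate: piecewise linear, threshold Tx, slope 1,
    saturating at ``gx_sat``."""
    return np.clip(x - params.Tx, 0.0, params.gx_sat)


def g_y(y: np.ndarray, params: ModelParams) -> np.ndarray:
    """Inhibitory firing rate: threshold Ty, then two linear segments with
    slopes ``gy_slopes`` meeting at ``gy_knee`` above threshold; unbounded."""
    s1, s2 = params.gy_slopes
    v = y - params.Ty
    return s1 * np.clip(v, 0.0, params.gy_knee) + s2 * np.maximum(
        v - params.gy_knee, 0.0
    )


def _wrap_half_pi(a: np.ndarray | float):
    """Wrap an angle into (-pi/2, pi/2]."""
    return -((-a + _PI / 2) % _PI) + _PI / 2


def _lateral_tables(
    params: ModelParams, dilation: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate the J and W spatial tables at one dilation factor.

    Geometry (distances, gates) is computed in scale-grid units
    d = |Delta| / dilation; weights are divided by dilation^2 so a spatial
    pattern and its dilated copy receive equal lateral input from the
    denser (undecimated) fine grid.
    """
    R_px = min(int(round(params.conn_radius * dilation)), params.max_reach_px)
    R_px = max(R_px, 1)
    K = 2 * R_px + 1
    dr, dc = np.meshgrid(
        np.arange(-R_px, R_px + 1), np.arange(-R_px, R_px + 1), indexing="ij"
    )
    d_px = np.hypot(dr, dc)
    d = d_px / dilation
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.arctan2(dr, dc)
    valid = (d_px > 0) & (d <= params.conn_radius)
    thetas = np.arange(N_ORIENT) * _PI / 4
    J = np.zeros((N_ORIENT, N_ORIENT, K, K))
    W = np.zeros_like(J)
    dsafe = np.where(valid, d, 1.0)
    for it, th_post in enumerate(thetas):
        for iu, th_pre in enumerate(thetas):
            dth = abs(float(_wrap_half_pi(th_post - th_pre)))
            a1 = _wrap_half_pi(th_post - phi)
            a2 = _wrap_half_pi(th_pre - phi)
            swap = np.abs(a1) > np.abs(a2)
            a1s = np.where(swap, a2, a1)
            a2s = np.where(swap, a1, a2)
            beta = 2.0 * np.abs(a1s) + 2.0 * np.sin(np.abs(a1s + a2s))
            bd = beta / dsafe
            cond_j = valid & (
                (beta < params.j_beta_gate)
                | (
                    (beta < params.j_beta_gate_wide)
                    & (np.abs(a1s) < params.j_theta_gate)
                    & (np.abs(a2s) < params.j_theta_gate)
                )
            )
            jv = params.j_strength * np.exp(
                -(bd**2) - 2.0 * bd**7 - dsafe * dsafe / params.j_dist_decay
            )
            J[it, iu] = np.where(cond_j, jv, 0.0)
            cond_w = (
                valid
                & ~cond_j
                & (d >= params.w_min_dist)
                & (beta >= params.w_beta_gate)
                & (dth < params.w_dtheta_gate)
                & (np.abs(a1s) >= params.w_theta_gate)
            )
            wv = (
                params.w_strength
                * (1.0 - np.exp(-params.w_sat * bd**1.5))
                * np.exp(-((dth / (_PI / 4)) ** 1.5))
            )
            W[it, iu] = np.where(cond_w, wv, 0.0)
    scale = dilation * dilation / params.lateral_gain
    return J / scale, W / scale


def build_connectivity(
    params: ModelParams, n_scales: int = 4, orientations: int = N_ORIENT
) -> ConnectivityKernel:
    """Construct the lateral coupling tables.

    Excitation J links near-coaligned, similarly oriented pairs along their
    common axis (bow-tie); inhibition W links flanking, non-aligned pairs.
    The geometric gates make the two sets disjoint.  Full coupling between
    scales s and s' is the spatial kernel — dilated by
    dilation_base**(min(s, s') - 1), i.e. lateral reach proportional to
    receptive-field size — times a Gaussian factor
    Gs(s, s') = exp(-(s - s')^2 / (2 sigma_scale^2)), truncated beyond
    ``scale_cutoff`` octaves.
    """
    if orientations != N_ORIENT:
        raise ValueError("the kernel is defined for 4 orientations (45 deg apart)")
    if params.conn_radius < 2:
        raise ValueError("conn_radius must be >= 2 to provide spatial context")
    s = np.arange(1, n_scales + 1, dtype=float)
    ds = s[:, None] - s[None, :]
    Gs = np.exp(-(ds**2) / (2.0 * params.sigma_scale**2))
    Gs[np.abs(ds) > params.scale_cutoff] = 0.0
    # the coarser RF of a pair sets the interaction metric ("beyond the RF")
    pair_dilation = params.dilation_base ** (np.maximum(s[:, None], s[None, :]) - 1.0)
    j_tables: dict[float, np.ndarray] = {}
    w_tables: dict[float, np.ndarray] = {}
    for dil in np.unique(pair_dilation):
        j_tables[float(dil)], w_tables[float(dil)] = _lateral_tables(params, dil)
    base_j, base_w = j_tables.get(1.0), w_tables.get(1.0)
    if base_j is None:
        base_j, base_w = _lateral_tables(params, 1.0)
    ps = params.psi
    dth_idx = np.abs(np.arange(orientations)[:, None] - np.arange(orientations))
    dth_idx = np.minimum(dth_idx, orientations - dth_idx)  # 0,1,2 -> 0,45,90 deg
    psi_mat = np.choose(dth_idx, [ps[0], ps[1], ps[2], ps[2]])
    return ConnectivityKernel(
        J=base_j,
        W=base_w,
        Gs=Gs,
        psi=psi_mat,
        radius=base_j.shape[-1] // 2,
        pair_dilation=pair_dilation,
        j_tables=j_tables,
        w_tables=w_tables,
    )


class CorticalNetwork:
    """Euler integrator for a fixed grid shape / kernel / parameter set.

    Precomputes the FFT representation of the lateral kernels for the
    padded grid so that one :meth:`step` costs a handful of batched FFTs.
    """

    def __init__(
        self,
        kernel: ConnectivityKernel,
        params: ModelParams,
        shape: tuple[int, int],
        disable_lateral: bool = False,
    ) -> None:
        self.kernel = kernel
        self.params = params
        self.shape = shape
        self.disable_lateral = disable_lateral
        self.n_scales = kernel.n_scales
        H, W = shape
        R = kernel.max_reach
        if params.boundary == "wrap":
            self._pad = 0
            hp, wp = H, W
        else:
            # symmetric padding cannot exceed the image size
            self._pad = min(R, H, W)
            hp, wp = H + 2 * self._pad, W + 2 * self._pad
        self._fft_shape = (next_fast_len(hp), next_fast_len(wp))
        if not disable_lateral:
            self._mhat_j = self._coupling_fft("J")
            self._mhat_w = self._coupling_fft("W")
        self._psi32 = kernel.psi.astype(np.float32)

    def _coupling_fft(self, which: str) -> np.ndarray:
        """conj(rFFT) of the full coupling tensor Gs(s,s') x dilated kernel,
        embedded with its center at index 0, ready for correlation (sum over
        source offsets).  Shape (S, O, S, O, hf, wf)."""
        S = self.n_scales
        hp, wp = self._fft_shape
        wf = wp // 2 + 1
        out = np.zeros((S, N_ORIENT, S, N_ORIENT, hp, wf), dtype=np.complex64)
        kern = self.kernel
        for s in range(S):
            for sp in range(S):
                g = kern.Gs[s, sp]
                if g == 0.0:
                    continue
                tab = kern.spatial_kernel(s, sp, which)
                r = tab.shape[-1] // 2
                emb = np.zeros((N_ORIENT, N_ORIENT, hp, wp), dtype=np.float32)
                # wrap the centered table so offset 0 lands at index 0;
                # reach can exceed the FFT grid only via explicit fold-in
                for dr in range(-r, r + 1):
                    for dcol in range(-r, r + 1):
                        v = tab[..., dr + r, dcol + r]
                        emb[..., dr % hp, dcol % wp] += v
                out[s, :, sp, :] = np.conj(rfft2(g * emb, axes=(-2, -1)))
        return out

    def _lateral(self, gx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Translation-invariant lateral sums sum J g_x and sum W g_x."""
        H, W = self.shape
        pad = self._pad
        hp, wp = self._fft_shape
        if pad:
            g = np.pad(gx, [(0, 0)] * 3 + [(pad, pad), (pad, pad)], mode="symmetric")
        else:
            g = gx
        buf = np.zeros(g.shape[:-2] + (hp, wp), dtype=np.float32)
        buf[..., : g.shape[-2], : g.shape[-1]] = g
        ghat = rfft2(buf, axes=(-2, -1))  # (2, S, O, hp, wf)
        out = []
        for mhat in (self._mhat_j, self._mhat_w):
            lhat = np.einsum("atbuhw,pbuhw->pathw", mhat, ghat)
            lat = irfft2(lhat, s=self._fft_shape, axes=(-2, -1))
            out.append(np.ascontiguousarray(lat[..., pad : pad + H, pad : pad + W]))
        return out[0], out[1]

    def _norm_pool(self, gx: np.ndarray) -> np.ndarray:
        """Squared local mean of g_x over orientations and a spatial box.

        The box scales with the receptive field (norm_radius in scale-grid
        units, dilated per scale), making the normalization pool a local
        contrast-energy measure at each scale."""
        p = self.params
        pool = gx.mean(axis=2)  # over orientations -> (2, S, H, W)
        if p.norm_radius > 0:
            mode = "mirror" if p.boundary == "mirror" else "wrap"
            for s in range(pool.shape[1]):
                r_px = int(round(p.norm_radius * p.dilation_base**s))
                r_px = min(r_px, p.max_reach_px)
                pool[:, s] = ndimage.uniform_filter(
                    pool[:, s], size=(1, 2 * r_px + 1, 2 * r_px + 1), mode=mode
                )
        return p.norm_strength * pool * pool

    def step(
        self,
        state: NetworkState,
        drive_at_t: np.ndarray,
        rng: np.random.Generator | None = None,
    ) -> NetworkState:
        """One forward-Euler update (in place on the state arrays)."""
        p = self.params
        x, y = state.x, state.y
        gx = g_x(x, p)
        gy = g_y(y, p)
        if self.disable_lateral:
            lat_j = lat_w = 0.0
        else:
            lat_j, lat_w = self._lateral(gx)
        psi_inh = np.einsum("tu,psuhw->psthw", self._psi32, gy)
        dx = -x - psi_inh + p.J0 * gx + lat_j + drive_at_t + p.I0
        if p.noise_amp > 0.0 and rng is not None:
            dx += rng.uniform(0.0, p.noise_amp, size=x.shape).astype(x.dtype)
        dy = -y + gx + lat_w + p.Ic + self._norm_pool(gx)[:, :, None]
        x += p.dt * dx
        y += p.dt * dy
        state.t += p.dt
        if not np.isfinite(x[0, 0, 0, 0, 0]):
            if not (np.isfinite(x).all() and np.isfinite(y).all()):
                raise FloatingPointError(
                    f"non-finite membrane potential at t={state.t:.2f} tau"
                )
        return state

    def initial_state(self, drive: np.ndarray) -> NetworkState:
        """Excitatory potentials start at the drive; inhibitory at zero."""
        return NetworkState(
            x=np.array(drive, dtype=np.float32, copy=True),
            y=np.zeros_like(drive, dtype=np.float32),
        )


@dataclass
class StaticResponse:
    """Temporally averaged network output for a static stimulus.

    ``alpha`` is g_x averaged over ``avg_window`` membrane time constants
    after the transient; ``alpha0`` is the context-free baseline from an
    identical run with the lateral connections J and W disabled.  ``trace``
    and ``trace0`` record the population-mean g_x at every Euler step of
    the averaging window (used for oscillation diagnostics).
    """

    alpha: np.ndarray
    alpha0: np.ndarray
    trace: np.ndarray
    trace0: np.ndarray


def step(
    state: NetworkState,
    drive_at_t: np.ndarray,
    kernel: ConnectivityKernel,
    params: ModelParams,
    rng: np.random.Generator | None = None,
) -> NetworkState:
    """Single Euler update (convenience wrapper building the operator).

    For multi-step simulations use :class:`CorticalNetwork` directly, which
    precomputes the kernel FFTs once.
    """
    net = CorticalNetwork(kernel, params, state.x.shape[-2:])
    return net.step(state, drive_at_t, rng)


def _as_drive_array(drive: RectifiedDrive | np.ndarray) -> np.ndarray:
    arr = drive.data if isinstance(drive, RectifiedDrive) else drive
    return np.asarray(arr, dtype=np.float32)


def _integrate(
    net: CorticalNetwork, drive: np.ndarray, params: ModelParams
) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(params.seed)
    state = net.initial_state(drive)
    n_settle = int(round(params.settle_time / params.dt))
    n_avg = int(round(params.avg_window / params.dt))
    for _ in range(n_settle):
        net.step(state, drive, rng)
    acc = np.zeros_like(state.x, dtype=np.float64)
    trace = np.empty(n_avg)
    for i in range(n_avg):
        net.step(state, drive, rng)
        gx = g_x(state.x, params)
        acc += gx
        trace[i] = gx.mean()
    return acc / n_avg, trace


def run_static(
    drive: RectifiedDrive | np.ndarray,
    kernel: ConnectivityKernel,
    params: ModelParams,
) -> StaticResponse:
    """Simulate a constant drive to the oscillatory steady state and return
    12-tau averages, together with the lateral-free baseline (same seed, so
    the noise realization matches)."""
    d = _as_drive_array(drive)
    shape = d.shape[-2:]
    net = CorticalNetwork(kernel, params, shape)
    alpha, trace = _integrate(net, d, params)
    net0 = CorticalNetwork(kernel, params, shape, disable_lateral=True)
    alpha0, trace0 = _integrate(net0, d, params)
    return StaticResponse(alpha=alpha, alpha0=alpha0, trace=trace, trace0=trace0)


@dataclass
class DynamicResponse:
    """Unaveraged excitatory output for a drive sequence.

    ``gx_frames`` holds the instantaneous g_x at the last Euler step of each
    stimulus frame (shape (n_frames, 2, S, 4, H, W), float32).
    ``probe_series`` holds g_x at every Euler step for the units selected by
    the ``probe`` index tuple, if given.
    """

    gx_frames: np.ndarray
    probe_series: np.ndarray | None
    steps_per_frame: int
    dt: float


def run_dynamic(
    drive_seq: RectifiedDrive | np.ndarray,
    kernel: ConnectivityKernel,
    params: ModelParams,
    frame_period: float = 1.0,
    probe: tuple | None = None,
    disable_lateral: bool = False,
) -> DynamicResponse:
    """Simulate a drive sequence advancing one frame per ``frame_period``
    membrane time constants.

    The network first settles on the initial frame for ``settle_time`` tau;
    the returned series then starts at frame 0.  ``probe`` is a numpy index
    tuple into (2, S, 4, H, W) whose units are recorded at every Euler step.
    """
    d = _as_drive_array(drive_seq)
    if d.ndim != 6:
        raise ValueError("drive_seq must have shape (F, 2, S, O, H, W)")
    n_frames = d.shape[0]
    shape = d.shape[-2:]
    spf = int(round(frame_period / params.dt))
    if spf < 1:
        raise ValueError("frame_period shorter than one Euler step")
    net = CorticalNetwork(kernel, params, shape, disable_lateral=disable_lateral)
    rng = np.random.default_rng(params.seed)
    state = net.initial_state(d[0])
    for _ in range(int(round(params.settle_time / params.dt))):
        net.step(state, d[0], rng)
    gx_frames = np.empty((n_frames,) + d.shape[1:], dtype=np.float32)
    series = [] if probe is not None else None
    for f in range(n_frames):
        for _ in range(spf):
            net.step(state, d[f], rng)
            if series is not None:
                series.append(g_x(state.x, params)[probe].copy())
        gx_frames[f] = g_x(state.x, params)
    return DynamicResponse(
        gx_frames=gx_frames,
        probe_series=np.array(series) if series is not None else None,
        steps_per_frame=spf,
        dt=params.dt,
    )
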