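"""Synthetic whole-cell currents of a use-dependent, thermally gated channel.

Generates temperature-ramp patch-clamp recordings with the statistical and
biophysical structure the Arrhenius analysis assumes, so the whole analysis
chain is testable without any recorded data.

Model
-----
The channel is a quasi-equilibrium two-state (closed/open) pore whose open
probability follows a van't Hoff law,

    Po(T) = 1 / (1 + exp((dH - T*dS - dG_agonist) / (R*T))),

plus an *irreversible sensitized gating mode* that accrues during
supra-threshold heating:

    ds/dt = sens_rate * max(0, T - sens_T) * (1 - s),      s(0) = s0,

so the sensitized fraction ``s`` never decreases (use-dependence).  The
effective open probability mixes the naive and sensitized modes,
``Po_eff = (1-s)*Po_naive + s*Po_sens`` with the sensitized mode carrying a
lower activation enthalpy and a lower midpoint.  This equilibrium +
mode-switch formalism is an explicit stand-in: the true gating kinetics of
strongly use-dependent thermoTRP channels are unknown and involve
irreversibility; the stand-in reproduces every observable the downstream
analysis consumes (steep initial limb, lowered Q10 after supra-threshold
sweeps, weak sub-threshold dependence, agonist potentiation, locked-open
behaviour).

The macroscopic current at holding potential ``vhold`` is

    I = N_g_max * q10_g^((T-25)/10) * Po_eff * (vhold - Vrev)
      + leak_g * q10_leak^((T-25)/10) * (vhold - leak_Vrev)
      + sub_g  * q10_sub^((T-25)/10) * Po_sub(T) * (vhold - leak_Vrev)
      + Gaussian noise,

in pA with conductances in nS and potentials in mV.  The third term is a
small sub-threshold background pathway: a low-enthalpy gate (``sub_dH``,
``sub_dS``; midpoint well below the activation threshold) that saturates
around the threshold.  Mixed with the ohmic leak (Q10 ~1.3) it produces the
weak background temperature dependence (apparent Q10 ~1.8 at 26-34 °C)
while the tail of the steep naive gate supplies the somewhat stronger
dependence just below threshold (~2.8 over 45-48 °C); a single-Q10 leak
cannot produce that temperature-dependent background slope.

Stimulus
--------
Heat stimuli are trains of ramps from a holding bath temperature to a
per-sweep peak.  The default ramp is an exponential approach whose asymptote
and rate are solved so that the maximal heating rate equals the configured
speed (default 35 °C/s) *and* the peak is reached exactly at ``rise_ms``
(a linear 1500-ms ramp cannot reach a 35 °C/s maximal speed).  Between
sweeps the bath relaxes exponentially back to base so that each sweep starts
from the holding temperature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy.optimize import brentq
from scipy.special import expit

from .arrhenius import R_GAS, ZERO_C

__all__ = [
    "RampProtocol",
    "GatingParams",
    "CurrentTrace",
    "SimulationError",
    "make_protocol",
    "open_probability",
    "simulate_cell",
    "make_cohort",
    "PRESETS",
    "DEFAULT_PROTOCOL",
]


class SimulationError(RuntimeError):
    """Raised when a simulated waveform is invalid (e.g. contains NaN)."""


# ---------------------------------------------------------------------------
# protocol
# ---------------------------------------------------------------------------

class RampProtocol(BaseModel):
    """Parametric description of a train of heat stimuli.

    ``inter_sweep_s`` is the start-to-start period of the ramps (3 s default:
    a 1.5 s rise followed by 1.5 s of re-cooling to base).  For the
    ``exp_approach`` shape the maximal heating rate equals ``max_speed``; for
    ``linear`` it is ``(T_peak - T_base) / rise_ms``.
    """

    model_config = {"frozen": True}

    T_base: float = 25.0          # °C
    T_peak: float = 57.0          # °C
    rise_ms: float = 1500.0
    inter_sweep_s: float = 3.0
    n_sweeps: int = Field(default=1, ge=1)
    shape: Literal["linear", "exp_approach"] = "exp_approach"
    max_speed: float = 35.0       # °C/s, exp_approach only
    sample_rate_hz: float = 1000.0
    agonist_sweeps: frozenset[int] = frozenset()

    @model_validator(mode="after")
    def _check(self):
        if self.rise_ms <= 0:
            raise ValueError("rise_ms must be positive")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.T_peak <= self.T_base:
            raise ValueError("T_peak must exceed T_base")
        if self.inter_sweep_s * 1e3 <= self.rise_ms:
            raise ValueError("inter_sweep_s must exceed the rise time")
        if self.shape == "exp_approach":
            span = self.T_peak - self.T_base
            if self.max_speed * self.rise_ms / 1e3 <= span:
                raise ValueError(
                    "max_speed too low to reach T_peak within rise_ms "
                    "(needs max_speed * rise > T_peak - T_base)"
                )
        return self


DEFAULT_PROTOCOL = RampProtocol()


def _exp_ramp_asymptote(span: float, speed: float, rise_s: float) -> float:
    """Asymptote excess A solving A*(1 - exp(-speed*rise/A)) = span.

    The ramp ``T(t) = T_base + A*(1 - exp(-k t))`` with ``k = speed / A``
    then has max slope ``speed`` at t=0 and reaches ``T_base + span`` exactly
    at ``rise_s``.
    """
    c = speed * rise_s

    def f(A):
        return A * (1.0 - np.exp(-c / A)) - span

    return brentq(f, span, 1e6 * span, xtol=1e-12, rtol=1e-14)


def make_protocol(protocol: RampProtocol):
    """Sample the temperature waveform of a full stimulus train.

    Returns
    -------
    (t, temp) : ndarray pair
        Global time in seconds and temperature in °C covering all sweeps,
        including the inter-sweep return to ``T_base``.
    """
    p = protocol
    dt = 1.0 / p.sample_rate_hz
    period = p.inter_sweep_s
    rise_s = p.rise_ms / 1e3
    n_per = int(round(period / dt))
    t_local = np.arange(n_per) * dt
    rising = t_local < rise_s
    span = p.T_peak - p.T_base
    temp = np.empty(n_per)
    if p.shape == "linear":
        temp[rising] = p.T_base + span * t_local[rising] / rise_s
    else:
        A = _exp_ramp_asymptote(span, p.max_speed, rise_s)
        k = p.max_speed / A
        temp[rising] = p.T_base + A * (1.0 - np.exp(-k * t_local[rising]))
    # exponential re-cool; time constant 1/10 of the cooling interval so the
    # residual at the next sweep start is span*e^-10 ~ 1.5e-3 °C
    tau = (period - rise_s) / 10.0
    cool = ~rising
    temp[cool] = p.T_base + span * np.exp(-(t_local[cool] - rise_s) / tau)
    t = np.arange(n_per * p.n_sweeps) * dt
    return t, np.tile(temp, p.n_sweeps)


# ---------------------------------------------------------------------------
# gating parameters
# ---------------------------------------------------------------------------

class GatingParams(BaseModel):
    """Thermodynamic and conductance parameters of the channel model.

    Units: enthalpies kJ/mol, entropies J/(mol K), conductances nS,
    potentials mV, temperatures °C (kelvin internally), noise pA.
    """

    model_config = {"frozen": True}

    dH: float = 295.0             # kJ/mol, naive-mode activation enthalpy
    dS: float = 893.0             # J/(mol K)
    dH_sens: float = 210.0        # kJ/mol, sensitized mode (must be < dH)
    dS_sens: float = 645.0        # J/(mol K)
    N_g_max: float = 25.0         # nS, channel count x unitary conductance
    Vrev: float = 0.0             # mV
    q10_g: float = 1.3            # open-channel conductance Q10
    leak_g: float = 1.0           # nS
    leak_Vrev: float = 0.0        # mV
    q10_leak: float = 1.3
    sub_g: float = 0.0            # nS, weak sub-threshold background pathway
    q10_sub: float = 1.0
    sub_dH: float = 0.0           # kJ/mol; > 0 gates the pathway by a low-
    sub_dS: float = 1.0           # J/(mol K); enthalpy van't Hoff Po (saturating)
    sens_T: float = 50.0          # °C, sensitization onset
    sens_rate: float = 1.0        # 1/(s K) above sens_T
    sens_softness: float | None = None  # °C; None = linear drive in (T - sens_T)
    s0: float = Field(default=0.0, ge=0.0, le=1.0)  # initial sensitized fraction
    agonist_dG: float = 0.0       # kJ/mol open-state stabilization when applied
    locked_open: bool = False
    vhold: float = -70.0          # mV
    noise_sd: float = 20.0        # pA
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        if self.dH <= 0 or self.dS <= 0:
            raise ValueError("dH and dS must be positive")
        if self.dH_sens >= self.dH:
            raise ValueError("sensitized-mode dH_sens must be below naive dH")
        if self.dH_sens / self.dS_sens > self.dH / self.dS * (1 + 1e-9):
            raise ValueError(
                "sensitized-mode midpoint (dH_sens/dS_sens) must not exceed "
                "the naive midpoint (dH/dS)"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        return self

    @property
    def midpoint_C(self) -> float:
        """Naive-mode half-activation temperature, °C."""
        return self.dH * 1e3 / self.dS - ZERO_C

    @property
    def midpoint_sens_C(self) -> float:
        """Sensitized-mode half-activation temperature, °C."""
        return self.dH_sens * 1e3 / self.dS_sens - ZERO_C


def open_probability(T_K, dH_kJ, dS_J, agonist_dG_kJ=0.0):
    """Two-state van't Hoff open probability.

    ``Po = 1 / (1 + exp((dH - T*dS - dG) / (R*T)))`` with ``dH`` and the
    agonist stabilisation ``dG`` in kJ/mol, ``dS`` in J/(mol K), ``T`` in
    kelvin.  Monotone increasing in T for dH, dS > 0; bounded in [0, 1].
    """
    T_K = np.asarray(T_K, dtype=float)
    if np.any(T_K <= 0):
        raise ValueError("absolute temperature must be positive")
    dG = dH_kJ * 1e3 - T_K * dS_J - agonist_dG_kJ * 1e3
    return expit(-dG / (R_GAS * T_K))


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------

@dataclass
class CurrentTrace:
    """One sweep of one cell: time, temperature and current records."""

    cell_id: str
    sweep: int
    t: np.ndarray        # s, strictly increasing
    temp: np.ndarray     # °C
    current: np.ndarray  # pA (inward negative at vhold = -70 mV)
    vhold: float = -70.0
    agonist: bool = False

    def __post_init__(self):
        if not (len(self.t) == len(self.temp) == len(self.current)):
            raise ValueError("t, temp and current must have equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")


def _sensitized_fraction(t, temp, sens_T, sens_rate, s0=0.0, softness=None):
    """Exact integral of ds/dt = drive(T) * (1-s); non-decreasing.

    The drive is zero at and below ``sens_T``.  With ``softness=None`` it is
    the linear ``sens_rate * (T - sens_T)``; with a softness scale ``d`` (°C)
    it is ``sens_rate * d * (exp((T - sens_T)/d) - 1)``, an Arrhenius-like
    thermal-activation drive whose log-linear growth (slope ``1/d`` per °C)
    produces a log-linear current takeoff above the sensitization
    temperature.  The two agree to first order just above ``sens_T`` and the
    linear form is the ``d -> inf`` limit.
    """
    excess = np.maximum(0.0, temp - sens_T)
    if softness is None:
        drive = sens_rate * excess
    else:
        drive = sens_rate * softness * np.expm1(excess / softness)
    dt = np.diff(t, prepend=t[0])
    dt[0] = 0.0
    expo = np.cumsum(drive * dt)
    return 1.0 - (1.0 - s0) * np.exp(-expo)


def simulate_cell(params: GatingParams, protocol: RampProtocol) -> list[CurrentTrace]:
    """Simulate all sweeps of one cell under a ramp protocol.

    The sensitized fraction carries over from sweep to sweep (irreversible
    use-dependence across the stimulus train).  Returns one
    :class:`CurrentTrace` per sweep.
    """
    t, temp = make_protocol(protocol)
    T_K = temp + ZERO_C
    n_per = int(round(protocol.inter_sweep_s * protocol.sample_rate_hz))

    agonist_mask = np.zeros(t.size, dtype=bool)
    for k in protocol.agonist_sweeps:
        agonist_mask[k * n_per:(k + 1) * n_per] = True

    s = _sensitized_fraction(
        t, temp, params.sens_T, params.sens_rate, params.s0, params.sens_softness
    )
    dG_ag = np.where(agonist_mask, params.agonist_dG, 0.0)
    if params.locked_open:
        po_eff = np.ones_like(t)
    else:
        po_naive = open_probability(T_K, params.dH, params.dS, 0.0)
        po_sens = open_probability(T_K, params.dH_sens, params.dS_sens, 0.0)
        if np.any(dG_ag > 0):
            po_naive = np.where(
                dG_ag > 0,
                open_probability(T_K, params.dH, params.dS, params.agonist_dG),
                po_naive,
            )
            po_sens = np.where(
                dG_ag > 0,
                open_probability(T_K, params.dH_sens, params.dS_sens, params.agonist_dG),
                po_sens,
            )
        po_eff = (1.0 - s) * po_naive + s * po_sens

    scale = (temp - 25.0) / 10.0
    drive = params.vhold - params.Vrev
    leak_drive = params.vhold - params.leak_Vrev
    sub_po = (
        open_probability(T_K, params.sub_dH, params.sub_dS)
        if params.sub_dH > 0
        else 1.0
    )
    current = (
        params.N_g_max * params.q10_g ** scale * po_eff * drive
        + params.leak_g * params.q10_leak ** scale * leak_drive
        + params.sub_g * params.q10_sub ** scale * sub_po * leak_drive
    )
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        current = current + rng.normal(0.0, params.noise_sd, size=current.shape)
    if not np.all(np.isfinite(current)):
        raise SimulationError("non-finite current in simulated waveform")

    traces = []
    for k in range(protocol.n_sweeps):
        sl = slice(k * n_per, (k + 1) * n_per)
        traces.append(
            CurrentTrace(
                cell_id=f"cell{params.seed:04d}",
                sweep=k,
                t=t[sl].copy(),
                temp=temp[sl].copy(),
                current=current[sl].copy(),
                vhold=params.vhold,
                agonist=bool(k in protocol.agonist_sweeps),
            )
        )
    return traces


# ---------------------------------------------------------------------------
# cohort presets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Preset:
    params: dict
    protocol: dict = field(default_factory=dict)
    # log-normal sigma applied multiplicatively per cell
    jitter_dH: float = 0.0
    jitter_mid: float = 0.0        # °C, normal jitter on mode midpoints
    jitter_gain: float = 0.0       # log-normal sigma on N_g_max and leaks
    jitter_speed: float = 0.0      # °C/s, normal jitter on max ramp speed
    jitter_sens_rate: float = 0.0  # log-normal sigma on sens_rate


#: Named phenotype presets.  The wild_type thermodynamics and sensitization
#: rate are calibrated so the packaged pipeline reproduces the printed
#: wild-type cohort statistics; the mutant-like presets encode the
#: qualitative phenotypes (tonic sensitized activity, heat resistance,
#: constitutively open).
PRESETS: dict[str, _Preset] = {
    "wild_type": _Preset(
        params=dict(
            dH=355.0, dS=355.0e3 / (58.5 + ZERO_C),
            dH_sens=248.0, dS_sens=248.0e3 / (56.5 + ZERO_C),
            N_g_max=19.0, leak_g=0.35, q10_leak=1.3,
            sub_g=2.42, q10_sub=1.0,
            sub_dH=90.0, sub_dS=90.0e3 / (48.0 + ZERO_C),
            sens_T=49.3, sens_rate=0.45, noise_sd=20.0,
        ),
        jitter_dH=0.06, jitter_mid=1.2, jitter_gain=0.28,
        jitter_speed=2.0, jitter_sens_rate=0.30,
    ),
    "sensitized_chimera": _Preset(
        params=dict(
            dH=330.0, dS=330.0e3 / (58.5 + ZERO_C),
            dH_sens=95.0, dS_sens=95.0e3 / (42.0 + ZERO_C),
            N_g_max=19.0, leak_g=0.35, q10_leak=1.3,
            sub_g=2.42, q10_sub=1.0,
            sub_dH=90.0, sub_dS=90.0e3 / (48.0 + ZERO_C),
            sens_T=40.0, sens_rate=3.0, s0=1.0, noise_sd=20.0,
        ),
        jitter_dH=0.06, jitter_mid=1.2, jitter_gain=0.28, jitter_speed=2.0,
    ),
    "heat_resistant": _Preset(
        params=dict(
            dH=330.0, dS=330.0e3 / (70.0 + ZERO_C),
            dH_sens=248.0, dS_sens=248.0e3 / (66.0 + ZERO_C),
            N_g_max=6.0, leak_g=0.35, q10_leak=1.3,
            sub_g=2.42, q10_sub=1.0,
            sub_dH=90.0, sub_dS=90.0e3 / (48.0 + ZERO_C),
            sens_T=62.0, sens_rate=0.62, noise_sd=20.0,
        ),
        jitter_dH=0.06, jitter_mid=1.5, jitter_gain=0.28, jitter_speed=2.0,
    ),
    "locked_open": _Preset(
        params=dict(
            dH=330.0, dS=330.0e3 / (58.5 + ZERO_C),
            dH_sens=248.0, dS_sens=248.0e3 / (56.5 + ZERO_C),
            N_g_max=28.0, leak_g=0.35, q10_leak=1.3,
            locked_open=True, noise_sd=20.0,
        ),
        jitter_gain=0.28, jitter_speed=2.0,
    ),
}
# DTT-reduced disulfide mutant behaves like wild type
PRESETS["dtt_rescued"] = PRESETS["wild_type"]


def make_cohort(
    preset: str,
    n_cells: int,
    seed: int,
    protocol: RampProtocol | None = None,
    **param_overrides,
) -> list[list[CurrentTrace]]:
    """Simulate a cohort of cells under a named phenotype preset.

    Per-cell variability mimics the cell-to-cell spread of thresholds and
    Q10 values seen in whole-cell cohorts: log-normal jitter on the
    activation enthalpy, gains and sensitization rate, normal jitter on the
    mode midpoints and on the maximal ramp speed (the realized heating speed
    varies between recordings and co-determines the apparent Q10 through the
    sensitization dynamics).  Deterministic for a fixed seed.

    Returns a list of cells, each a list of per-sweep traces.
    """
    if preset not in PRESETS:
        raise KeyError(f"unknown preset {preset!r}; known: {sorted(PRESETS)}")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    cfg = PRESETS[preset]
    base_proto = protocol if protocol is not None else RampProtocol(**cfg.protocol)
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n_cells):
        p = dict(cfg.params)
        p.update(param_overrides)
        dH = p["dH"] * float(np.exp(rng.normal(0.0, cfg.jitter_dH)))
        mid_K = p["dH"] * 1e3 / p["dS"] + rng.normal(0.0, cfg.jitter_mid)
        p["dH"], p["dS"] = dH, dH * 1e3 / mid_K
        if "dH_sens" in p and not p.get("locked_open", False):
            dHs = p["dH_sens"] * float(np.exp(rng.normal(0.0, cfg.jitter_dH)))
            dHs = min(dHs, 0.95 * dH)
            mids_K = min(
                p["dH_sens"] * 1e3 / p["dS_sens"] + rng.normal(0.0, cfg.jitter_mid),
                mid_K,
            )
            p["dH_sens"], p["dS_sens"] = dHs, dHs * 1e3 / mids_K
        for g in ("N_g_max", "leak_g", "sub_g"):
            if p.get(g):
                p[g] = p[g] * float(np.exp(rng.normal(0.0, cfg.jitter_gain)))
        if "sens_rate" in p and cfg.jitter_sens_rate:
            p["sens_rate"] = p["sens_rate"] * float(
                np.exp(rng.normal(0.0, cfg.jitter_sens_rate))
            )
        speed = base_proto.max_speed + rng.normal(0.0, cfg.jitter_speed)
        speed = max(speed, (base_proto.T_peak - base_proto.T_base)
                    / (base_proto.rise_ms / 1e3) * 1.02)
        proto = base_proto.model_copy(update={"max_speed": speed}) \
            if base_proto.shape == "exp_approach" else base_proto
        p["seed"] = int(rng.integers(0, 2**31 - 1))
        params = GatingParams(**p)
        cell = simulate_cell(params, proto)
        for tr in cell:
            tr.cell_id = f"{preset}_{i:03d}"
        cohort.append(cell)
    return cohort
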