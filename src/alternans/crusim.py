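"""Stochastic 3D lattice of coupled Ca2+ release units (CRUs) with troponin buffering.

The model is a self-contained minimal realization of the "3R" mechanism of
Ca2+ alternans — Randomness of spark firing, Recruitment of neighbouring
CRUs, and Refractoriness of release — on a 3D lattice of dyads. Each CRU
carries a cytosolic sub-volume, a network-SR and a junctional-SR
compartment:

* stochastic spark ignition: per-step Bernoulli with rate increasing in
  local cytosolic Ca2+ (recruitment) and in junctional-SR load;
* spark termination on fractional junctional-SR depletion followed by a
  fixed refractory period;
* SERCA uptake (Hill form), SR leak, NSR->jSR refill, and nearest-neighbour
  diffusive coupling of cytosolic and network-SR Ca2+ with no-flux
  boundaries;
* troponin C as the only time-resolved buffer,
  J_trpn = k_on (B_t - [CaT]) [Ca2+] - k_off [CaT]; all faster buffers
  (calmodulin-like in the cytosol, calsequestrin in the jSR) use the
  rapid-buffering equilibrium. To keep closed-cell mass conservation exact
  the state tracks *total* (free + rapid-bound) Ca2+ per compartment and
  recovers free Ca2+ from the binding quadratic every step.

Pacing applies a brief trigger flux into every dyad (emulating L-type
channel openings). Voltage is a prescribed action-potential waveform by
default (``clamped_waveform``); an optional phenomenological
``coupled_minimal_ap`` mode lets a Ca2+-sensitive inward current feed
voltage so that voltage alternans can emerge secondary to Ca2+ alternans.

Random numbers come from one counter-based stream per CRU derived from the
master seed (a splitmix64-style hash of seed, CRU index and step), so
trajectories are reproducible and lattice-size changes do not reshuffle
the randomness of existing CRUs.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .exceptions import IntegrationFailureError, InvalidParameterError
from .traces import ALTERNANS_THRESHOLD

__all__ = [
    "TroponinBufferParams",
    "SercaParams",
    "LatticeSpec",
    "SparkParams",
    "FluxParams",
    "SimParams",
    "PacingProtocol",
    "CellState",
    "SimTrace",
    "BifurcationResult",
    "troponin_flux",
    "troponin_equilibrium",
    "make_default_params",
    "init_state",
    "step",
    "run",
    "run_paced",
    "scan_pcl",
    "detect_alternans",
    "check_conservation",
]


# ---------------------------------------------------------------------------
# Parameters


@dataclass
class TroponinBufferParams:
    """Troponin C Ca2+ buffering; k_on/k_off in (uM ms)^-1 / ms^-1."""

    k_on: float = 0.0327
    k_off: float = 0.5  # 0.1 for the slowed-unbinding variant
    b_total: float = 70.0  # uM total troponin sites (model-family standard)

    def __post_init__(self):
        if min(self.k_on, self.k_off, self.b_total) <= 0:
            raise InvalidParameterError("troponin parameters must be positive")


@dataclass
class SercaParams:
    """SERCA uptake v_max * c^h / (c^h + kd^h), uM/ms."""

    v_max: float = 0.024
    kd: float = 0.25  # uM
    hill: float = 2.0

    def __post_init__(self):
        if min(self.v_max, self.kd, self.hill) <= 0:
            raise InvalidParameterError("SERCA parameters must be positive")


@dataclass
class LatticeSpec:
    """3D CRU lattice dimensions and diffusive coupling rates (ms^-1)."""

    nx: int = 20
    ny: int = 5
    nz: int = 5
    coupling_cyto: float = 0.6
    coupling_sr: float = 0.1

    def __post_init__(self):
        if self.nx * self.ny * self.nz < 1:
            raise InvalidParameterError("lattice must contain at least one CRU")

    @property
    def n_cru(self) -> int:
        return self.nx * self.ny * self.nz


@dataclass
class SparkParams:
    """Spark ignition/termination/refractoriness parameters."""

    ignition_rate_base: float = 0.3  # ms^-1 at c = 1 uM and reference load
    ignition_ca_exponent: float = 6.0
    release_conductance: float = 2e-3  # ms^-1, cytosolic-volume units
    spark_termination_jsr_fraction: float = 0.35  # of jsr_ref free Ca
    refractory_tau: float = 80.0  # ms
    jsr_ref: float = 400.0  # uM free jSR; reference of the load gate
    load_exponent: float = 16.0  # steepness of release-load recruitment
    trigger_rate: float = 8.0  # ms^-1 ignition boost during the stimulus

    def __post_init__(self):
        if self.refractory_tau <= 0:
            raise InvalidParameterError("refractory_tau must be positive")
        vals = dataclasses.astuple(self)
        if any(v < 0 for v in vals):
            raise InvalidParameterError("spark parameters must be non-negative")


@dataclass
class FluxParams:
    """Non-release fluxes, compartment volumes and fast buffers."""

    leak_rate: float = 1.5e-5  # ms^-1, NSR->cyto
    ncx_scale: float = 0.008  # ms^-1, cyto Ca extrusion (open cell)
    trigger_flux: float = 0.3  # uM/ms into each dyad during the stimulus
    trigger_duration: float = 2.0  # ms
    background_influx: float = 8e-4  # uM/ms sarcolemmal leak in (open cell)
    v_nsr: float = 0.015  # NSR volume / cytosolic volume
    v_jsr: float = 0.02  # jSR volume / cytosolic volume
    jsr_refill_tau: float = 15.0  # ms, NSR->jSR equilibration
    fast_buffer_total: float = 3.0  # uM cytosolic rapid buffer beside troponin
    fast_buffer_kd: float = 0.6  # uM
    csq_total: float = 400.0  # uM calsequestrin in jSR volume
    csq_kd: float = 600.0  # uM
    closed_cell: bool = False  # disable all sarcolemmal fluxes

    def __post_init__(self):
        if min(self.v_nsr, self.v_jsr, self.jsr_refill_tau) <= 0:
            raise InvalidParameterError("volumes and refill tau must be positive")


@dataclass
class SimParams:
    """Full parameterization of the CRU-network myocyte model."""

    lattice: LatticeSpec = field(default_factory=LatticeSpec)
    troponin: TroponinBufferParams = field(default_factory=TroponinBufferParams)
    serca: SercaParams = field(default_factory=SercaParams)
    spark: SparkParams = field(default_factory=SparkParams)
    fluxes: FluxParams = field(default_factory=FluxParams)
    voltage_mode: str = "clamped_waveform"  # or "coupled_minimal_ap"
    dt: float = 0.05  # ms
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.dt <= 0.1:
            raise InvalidParameterError("dt must lie in (0, 0.1] ms")
        if self.voltage_mode not in ("clamped_waveform", "coupled_minimal_ap"):
            raise InvalidParameterError(f"unknown voltage_mode {self.voltage_mode!r}")

    def replace(self, **kw) -> "SimParams":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "SimParams":
        return cls(
            lattice=LatticeSpec(**d["lattice"]),
            troponin=TroponinBufferParams(**d["troponin"]),
            serca=SercaParams(**d["serca"]),
            spark=SparkParams(**d["spark"]),
            fluxes=FluxParams(**d["fluxes"]),
            voltage_mode=d.get("voltage_mode", "clamped_waveform"),
            dt=d.get("dt", 0.05),
            seed=d.get("seed", 0),
        )

    @classmethod
    def from_json(cls, text: str) -> "SimParams":
        return cls.from_dict(json.loads(text))

    def to_yaml(self) -> str:
        import yaml

        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "SimParams":
        import yaml

        return cls.from_dict(yaml.safe_load(text))


@dataclass
class PacingProtocol:
    """Periodic field-stimulation protocol."""

    pcl: float = 400.0  # ms
    n_beats: int = 34
    n_discard: int = 18

    def __post_init__(self):
        if self.pcl <= 0:
            raise InvalidParameterError("PCL must be positive")
        if not 0 <= self.n_discard < self.n_beats:
            raise InvalidParameterError("need 0 <= n_discard < n_beats")


# ---------------------------------------------------------------------------
# State


@dataclass
class CellState:
    """Per-CRU lattice state plus global voltage and time.

    ``ca_total_cyto`` and ``ca_total_jsr`` are *total* (free + rapid-bound)
    concentrations; free values are recovered from the binding quadratic.
    """

    ca_total_cyto: np.ndarray  # uM, free + fast-buffer-bound
    ca_trpn: np.ndarray  # uM bound to troponin
    ca_nsr: np.ndarray  # uM free (no NSR buffer)
    ca_total_jsr: np.ndarray  # uM, free + CSQ-bound
    spark_active: np.ndarray  # int8
    refractory_clock: np.ndarray  # ms remaining
    v_membrane: float = -80.0
    time: float = 0.0
    step_count: int = 0

    def copy(self) -> "CellState":
        return CellState(
            self.ca_total_cyto.copy(),
            self.ca_trpn.copy(),
            self.ca_nsr.copy(),
            self.ca_total_jsr.copy(),
            self.spark_active.copy(),
            self.refractory_clock.copy(),
            self.v_membrane,
            self.time,
            self.step_count,
        )

    def ca_cyto_free(self, p: SimParams) -> np.ndarray:
        return _free_from_total(
            self.ca_total_cyto, p.fluxes.fast_buffer_total, p.fluxes.fast_buffer_kd
        )

    def ca_jsr_free(self, p: SimParams) -> np.ndarray:
        return _free_from_total(self.ca_total_jsr, p.fluxes.csq_total, p.fluxes.csq_kd)

    def total_ca(self, p: SimParams) -> float:
        """Volume-weighted total Ca2+ per unit cytosolic volume (uM)."""
        f = p.fluxes
        per_cru = (
            self.ca_total_cyto
            + self.ca_trpn
            + f.v_nsr * self.ca_nsr
            + f.v_jsr * self.ca_total_jsr
        )
        return float(per_cru.mean())


@dataclass
class SimTrace:
    """Whole-cell traces recorded during a run (1-ms sampling by default)."""

    time: np.ndarray  # ms
    voltage: np.ndarray  # mV
    ca_cyto: np.ndarray  # uM, mean free cytosolic
    ca_sr: np.ndarray  # uM, volume-weighted mean free SR
    total_ca: np.ndarray  # uM, conservation diagnostic
    spark_rate: np.ndarray  # CRU ignitions per CRU per recording interval
    beat_peaks: np.ndarray  # peak free cytosolic Ca per recorded beat
    beat_diastolic: np.ndarray  # pre-beat minima
    stimulus_times: np.ndarray  # ms
    pcl: float = math.nan
    captured: np.ndarray | None = None
    capture_warning: bool = False


@dataclass
class BifurcationResult:
    """Last-two-beat peak Ca vs pacing cycle length (the bifurcation scan)."""

    pcl_values: np.ndarray
    peaks: np.ndarray  # shape (n_pcl, 2)
    alternans_flags: np.ndarray  # bool per PCL (majority-voted if multi-seed)
    onset_pcl: float  # smallest scanned PCL without alternans
    threshold: float = ALTERNANS_THRESHOLD
    per_seed_flags: np.ndarray | None = None  # (n_seed, n_pcl) when multi-seed


# ---------------------------------------------------------------------------
# Closed-form pieces


def troponin_flux(ca_cyto, ca_trpn, p: TroponinBufferParams):
    """Net Ca2+ binding flux onto troponin (uM/ms; positive = binding)."""
    ca_cyto = np.asarray(ca_cyto, dtype=float)
    ca_trpn = np.asarray(ca_trpn, dtype=float)
    if (ca_trpn > p.b_total + 1e-12).any() or (ca_trpn < 0).any():
        raise InvalidParameterError("ca_trpn must lie in [0, b_total]")
    if (ca_cyto < 0).any():
        raise InvalidParameterError("ca_cyto must be >= 0")
    out = p.k_on * (p.b_total - ca_trpn) * ca_cyto - p.k_off * ca_trpn
    return float(out) if out.ndim == 0 else out


def troponin_equilibrium(ca_cyto: float, p: TroponinBufferParams) -> float:
    """Equilibrium troponin-bound Ca2+: B_t * c / (c + k_off/k_on)."""
    return p.b_total * ca_cyto / (ca_cyto + p.k_off / p.k_on)


def _free_from_total(total, b, kd):
    """Free Ca2+ from total in a compartment with one rapid buffer.

    Solves c + b*c/(kd + c) = total for c (positive root of the quadratic).
    """
    total = np.asarray(total, dtype=float)
    q = kd + b - total
    return 0.5 * (-q + np.sqrt(q * q + 4.0 * kd * total))


def _total_from_free(free, b, kd):
    free = np.asarray(free, dtype=float)
    return free + b * free / (kd + free)


def detect_alternans(peaks, threshold: float = ALTERNANS_THRESHOLD) -> tuple[float, bool]:
    """Beat-to-beat alternation of a recorded peak sequence.

    The ratio is the absolute difference between even- and odd-beat mean
    peaks over the grand mean — identical to the relative last-two-peak
    separation when only two peaks are recorded, and an average of it
    (same signal, less lattice shot noise) when more are. The flag is set
    above ``threshold`` (default 5%).
    """
    p = np.asarray(peaks, dtype=float)
    if len(p) < 2:
        raise InvalidParameterError("need at least two recorded peaks")
    ratio = abs(p[0::2].mean() - p[1::2].mean()) / p.mean()
    return float(ratio), bool(ratio > threshold)


# ---------------------------------------------------------------------------
# Defaults

_FULL_LATTICE = (100, 20, 10)
_TEST_LATTICE = (20, 5, 5)


def make_default_params(variant: str = "control", scale: str = "test") -> SimParams:
    """Calibrated default parameter sets.

    ``variant='control'`` uses troponin k_off = 0.5 ms^-1;
    ``variant='reduced_koff'`` uses 0.1 ms^-1 (the slowed-unbinding
    myofilament); everything else is identical between the two. The
    ``test`` scale is a 20x5x5 lattice (500 CRUs) calibrated so that the
    control variant paces 1:1 without alternans across PCL 300-700 ms while
    the reduced-k_off variant alternates below 500 ms; ``full`` selects the
    100x20x10 (20,000-CRU) lattice with the same per-CRU parameters.
    """
    if variant not in ("control", "reduced_koff"):
        raise InvalidParameterError("variant must be 'control' or 'reduced_koff'")
    if scale not in ("test", "full"):
        raise InvalidParameterError("scale must be 'test' or 'full'")
    dims = _TEST_LATTICE if scale == "test" else _FULL_LATTICE
    k_off = 0.5 if variant == "control" else 0.1
    return SimParams(
        lattice=LatticeSpec(*dims),
        troponin=TroponinBufferParams(k_off=k_off),
        serca=SercaParams(),
        spark=SparkParams(),
        fluxes=FluxParams(),
    )


def init_state(p: SimParams, ca_cyto: float = 0.1, ca_sr: float = 900.0) -> CellState:
    """Quiescent initial state at a given free cytosolic and SR Ca2+."""
    n = p.lattice.n_cru
    f = p.fluxes
    u0 = _total_from_free(ca_cyto, f.fast_buffer_total, f.fast_buffer_kd)
    w0 = _total_from_free(ca_sr, f.csq_total, f.csq_kd)
    return CellState(
        ca_total_cyto=np.full(n, u0),
        ca_trpn=np.full(n, troponin_equilibrium(ca_cyto, p.troponin)),
        ca_nsr=np.full(n, float(ca_sr)),
        ca_total_jsr=np.full(n, w0),
        spark_active=np.zeros(n, dtype=np.int8),
        refractory_clock=np.zeros(n),
    )


# ---------------------------------------------------------------------------
# Numba kernel

_U64 = np.uint64


@njit(cache=True, inline="always")
def _rng_u01(seed, cru, step):
    """Counter-based uniform in [0,1): splitmix64 finalizer of (seed, cru, step)."""
    x = (
        _U64(seed) * _U64(0x9E3779B97F4A7C15)
        + _U64(cru) * _U64(0xD1B54A32D192ED03)
        + _U64(step) * _U64(0x8CB92BA72F3D8DD7)
    )
    x = (x ^ (x >> _U64(30))) * _U64(0xBF58476D1CE4E5B9)
    x = (x ^ (x >> _U64(27))) * _U64(0x94D049BB133111EB)
    x = x ^ (x >> _U64(31))
    return x / 1.8446744073709552e19


@njit(cache=True)
def _advance(
    u, b, n_sr, w, spark, refr,  # state arrays (modified in place)
    neighbors,  # (N, 6) int32, -1 marks a missing neighbour
    P,  # flat float64 parameter vector (see _pack_params)
    seed, step0, n_steps,
    stim_period_steps, stim_dur_steps, n_stim,  # pacing (<=0 disables)
    v0, coupled_ap,
    rec_every, rec_v, rec_c, rec_sr, rec_m, rec_f,  # recording buffers
):
    (kon, koff, btot, vmax, skd, shill, kig, cexp, grel, fterm, rtau, jref,
     lexp, trig_rate, gleak, gncx, jtrig, bg_in, vn, vj, refill_tau,
     bf, kf, bcsq, kcsq, closed, dc, dn, dt) = (
        P[0], P[1], P[2], P[3], P[4], P[5], P[6], P[7], P[8], P[9], P[10],
        P[11], P[12], P[13], P[14], P[15], P[16], P[17], P[18], P[19], P[20],
        P[21], P[22], P[23], P[24], P[25], P[26], P[27], P[28],
    )
    N = u.shape[0]
    j_term = fterm * jref
    v = v0
    c = np.empty(N)
    j = np.empty(N)
    du = np.empty(N)
    dn_arr = np.empty(N)
    rec_i = 0
    bad_field = 0
    bad_time = -1.0
    n_ignitions = 0

    for s in range(n_steps):
        g_step = step0 + s
        # free Ca from totals (rapid-buffer quadratics)
        for i in range(N):
            q = kf + bf - u[i]
            c[i] = 0.5 * (-q + math.sqrt(q * q + 4.0 * kf * u[i]))
            qj = kcsq + bcsq - w[i]
            j[i] = 0.5 * (-qj + math.sqrt(qj * qj + 4.0 * kcsq * w[i]))

        # stimulus window?
        stim_on = False
        if stim_period_steps > 0:
            beat = g_step // stim_period_steps
            phase = g_step - beat * stim_period_steps
            if beat < n_stim and phase < stim_dur_steps:
                stim_on = True

        mean_c = 0.0
        for i in range(N):
            ci = c[i]
            ji = j[i]
            # deterministic fluxes (cytosolic-volume uM/ms)
            ch = ci**shill
            j_serca = vmax * ch / (ch + skd**shill)
            j_leak = gleak * (n_sr[i] - ci)
            j_rel = grel * (ji - ci) if spark[i] == 1 else 0.0
            j_trpn = kon * (btot - b[i]) * ci - koff * b[i]
            # diffusion (no-flux boundaries)
            lap_c = 0.0
            lap_n = 0.0
            for k in range(6):
                nb = neighbors[i, k]
                if nb >= 0:
                    lap_c += c[nb] - ci
                    lap_n += n_sr[nb] - n_sr[i]
            j_sarco = 0.0
            if closed == 0.0:
                j_sarco = bg_in - gncx * ci
                if stim_on:
                    j_sarco += jtrig
            du[i] = dt * (
                j_rel + j_leak - j_serca - j_trpn + dc * lap_c + j_sarco
            )
            b[i] += dt * j_trpn
            j_refill = (n_sr[i] - ji) / refill_tau  # jSR-volume units
            dn_arr[i] = dt * (
                (j_serca - j_leak) / vn - j_refill * (vj / vn) + dn * lap_n
            )
            w[i] += dt * (j_refill - j_rel / vj)

            # spark ignition / termination / refractoriness
            if spark[i] == 1:
                if ji < j_term:
                    spark[i] = 0
                    refr[i] = rtau
            else:
                if refr[i] > 0.0:
                    refr[i] -= dt
                else:
                    load = ji / jref
                    if load < 0.0:
                        load = 0.0
                    gate = load**lexp
                    rate = kig * ci**cexp * gate
                    if stim_on:
                        rate += trig_rate * gate
                    pfire = rate * dt
                    if pfire > 0.0 and _rng_u01(seed, i, g_step) < pfire:
                        spark[i] = 1
                        n_ignitions += 1
            mean_c += ci
        mean_c /= N

        for i in range(N):
            u[i] += du[i]
            n_sr[i] += dn_arr[i]
            if u[i] < 0.0:
                u[i] = 0.0
            if w[i] < 0.0:
                w[i] = 0.0
            if n_sr[i] < 0.0:
                n_sr[i] = 0.0

        # membrane potential
        if coupled_ap == 1:
            # leak repolarization toward rest plus a Ca-activated inward
            # current with a +10 mV reversal: voltage rides the Ca transient
            ca_drive = mean_c - 0.1
            if ca_drive < 0.0:
                ca_drive = 0.0
            dv = -0.012 * (v + 80.0) + 0.02 * ca_drive * (10.0 - v)
            if stim_on:
                dv += 60.0
            v += dt * dv
        else:
            if stim_period_steps > 0:
                beat = g_step // stim_period_steps
                phase_ms = (g_step - beat * stim_period_steps) * dt
                apd = 0.6 * stim_period_steps * dt
                if apd > 320.0:
                    apd = 320.0
                if beat < n_stim:
                    up = 1.0 - math.exp(-phase_ms / 1.5)
                    rep = 1.0 / (1.0 + math.exp((phase_ms - apd) / 12.0))
                    v = -80.0 + 115.0 * up * rep
                else:
                    v = -80.0
            else:
                v = -80.0

        # recording + divergence check
        if rec_every > 0 and (g_step + 1) % rec_every == 0:
            mass = 0.0
            mc = 0.0
            msr = 0.0
            for i in range(N):
                mass += u[i] + b[i] + vn * n_sr[i] + vj * w[i]
                q = kf + bf - u[i]
                ci = 0.5 * (-q + math.sqrt(q * q + 4.0 * kf * u[i]))
                qj = kcsq + bcsq - w[i]
                ji = 0.5 * (-qj + math.sqrt(qj * qj + 4.0 * kcsq * w[i]))
                mc += ci
                msr += (vn * n_sr[i] + vj * ji) / (vn + vj)
            rec_v[rec_i] = v
            rec_c[rec_i] = mc / N
            rec_sr[rec_i] = msr / N
            rec_m[rec_i] = mass / N
            rec_f[rec_i] = n_ignitions / N
            n_ignitions = 0
            if not (math.isfinite(rec_c[rec_i]) and math.isfinite(rec_m[rec_i])):
                bad_field = 1
                bad_time = (g_step + 1) * dt
                rec_i += 1
                break
            rec_i += 1
    return rec_i, v, bad_field, bad_time


def _pack_params(p: SimParams) -> np.ndarray:
    t, sp, se, f, lat = p.troponin, p.spark, p.serca, p.fluxes, p.lattice
    return np.array(
        [
            t.k_on, t.k_off, t.b_total,
            se.v_max, se.kd, se.hill,
            sp.ignition_rate_base, sp.ignition_ca_exponent,
            sp.release_conductance, sp.spark_termination_jsr_fraction,
            sp.refractory_tau, sp.jsr_ref, sp.load_exponent, sp.trigger_rate,
            f.leak_rate, f.ncx_scale, f.trigger_flux, f.background_influx,
            f.v_nsr, f.v_jsr, f.jsr_refill_tau,
            f.fast_buffer_total, f.fast_buffer_kd, f.csq_total, f.csq_kd,
            1.0 if f.closed_cell else 0.0,
            lat.coupling_cyto, lat.coupling_sr,
            p.dt,
        ]
    )


def _neighbor_table(lat: LatticeSpec) -> np.ndarray:
    nx, ny, nz = lat.nx, lat.ny, lat.nz
    idx = np.arange(nx * ny * nz).reshape(nx, ny, nz)
    nb = np.full((nx * ny * nz, 6), -1, dtype=np.int32)
    shifts = [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)]
    for k, (dx, dy, dz) in enumerate(shifts):
        src = idx
        for x in range(nx):
            for y in range(ny):
                for z in range(nz):
                    X, Y, Z = x + dx, y + dy, z + dz
                    if 0 <= X < nx and 0 <= Y < ny and 0 <= Z < nz:
                        nb[src[x, y, z], k] = idx[X, Y, Z]
    return nb


# ---------------------------------------------------------------------------
# Drivers


def run(
    state: CellState,
    p: SimParams,
    duration_ms: float,
    pacing: PacingProtocol | None = None,
    record_dt_ms: float = 1.0,
    seed: int | None = None,
) -> SimTrace:
    """Advance the lattice for ``duration_ms`` and record whole-cell traces.

    ``state`` is advanced in place. ``pacing=None`` runs without a
    stimulus; otherwise the trigger fires every ``pacing.pcl`` ms starting
    at t=0 (relative to the state's current step counter).
    """
    dt = p.dt
    n_steps = int(round(duration_ms / dt))
    rec_every = max(1, int(round(record_dt_ms / dt)))
    n_rec = n_steps // rec_every
    rec_v = np.zeros(n_rec)
    rec_c = np.zeros(n_rec)
    rec_sr = np.zeros(n_rec)
    rec_m = np.zeros(n_rec)
    rec_f = np.zeros(n_rec)
    if pacing is None:
        period_steps, dur_steps, n_stim = 0, 0, 0
    else:
        period_steps = int(round(pacing.pcl / dt))
        dur_steps = max(1, int(round(p.fluxes.trigger_duration / dt)))
        n_stim = pacing.n_beats
    seed_val = p.seed if seed is None else seed
    rec_i, v, bad, bad_t = _advance(
        state.ca_total_cyto, state.ca_trpn, state.ca_nsr, state.ca_total_jsr,
        state.spark_active, state.refractory_clock,
        _neighbor_table(p.lattice), _pack_params(p),
        seed_val, state.step_count, n_steps,
        period_steps, dur_steps, n_stim,
        state.v_membrane, 1 if p.voltage_mode == "coupled_minimal_ap" else 0,
        rec_every, rec_v, rec_c, rec_sr, rec_m, rec_f,
    )
    if bad:
        raise IntegrationFailureError(
            f"non-finite cytosolic Ca at t = {bad_t:.3f} ms (dt too large?)",
            field="ca_cyto",
            time_ms=bad_t,
        )
    state.v_membrane = float(v)
    state.step_count += n_steps
    state.time += n_steps * dt
    t0 = (state.step_count - n_steps) * dt
    times = t0 + (np.arange(n_rec) + 1) * rec_every * dt
    stim_times = (
        t0 + np.arange(n_stim) * pacing.pcl if pacing is not None else np.array([])
    )
    return SimTrace(
        time=times[:rec_i],
        voltage=rec_v[:rec_i],
        ca_cyto=rec_c[:rec_i],
        ca_sr=rec_sr[:rec_i],
        total_ca=rec_m[:rec_i],
        spark_rate=rec_f[:rec_i],
        beat_peaks=np.array([]),
        beat_diastolic=np.array([]),
        stimulus_times=stim_times,
        pcl=pacing.pcl if pacing is not None else math.nan,
    )


def step(state: CellState, p: SimParams) -> CellState:
    """Advance the state by one time step ``p.dt`` (returns the same object)."""
    run(state, p, duration_ms=p.dt, record_dt_ms=p.dt)
    return state


def run_paced(
    p: SimParams,
    protocol: PacingProtocol,
    seed: int | None = None,
    state: CellState | None = None,
) -> SimTrace:
    """Pace a (fresh) cell for ``protocol.n_beats`` beats and collect peaks.

    The first ``protocol.n_discard`` beats are treated as the approach to
    the periodic attractor; ``beat_peaks`` holds the peak free cytosolic
    Ca2+ of the remaining beats. A failed-capture warning is attached when
    at least half of the recorded beats evoke no transient (peak below
    1.05x the beat's diastolic level).
    """
    if state is None:
        state = init_state(p)
    duration = protocol.n_beats * protocol.pcl
    trace = run(state, p, duration, pacing=protocol, seed=seed)
    rec_per_beat = int(round(protocol.pcl / (trace.time[1] - trace.time[0])))
    peaks, dias, captured = [], [], []
    for beat in range(protocol.n_discard, protocol.n_beats):
        lo, hi = beat * rec_per_beat, (beat + 1) * rec_per_beat
        window = trace.ca_cyto[lo:hi]
        if len(window) == 0:
            continue
        peak, dia = float(window.max()), float(window.min())
        peaks.append(peak)
        dias.append(dia)
        captured.append(peak >= 1.05 * dia)
    trace.beat_peaks = np.array(peaks)
    trace.beat_diastolic = np.array(dias)
    trace.captured = np.array(captured, dtype=bool)
    if len(captured) and np.mean(captured) < 0.5:
        trace.capture_warning = True
        warnings.warn(
            f"failed capture on >= half the recorded beats at PCL {protocol.pcl} ms",
            stacklevel=2,
        )
    return trace


DEFAULT_PCL_GRID = np.arange(300.0, 701.0, 50.0)


def scan_pcl(
    p: SimParams,
    pcl_grid=None,
    protocol: PacingProtocol | None = None,
    seeds=None,
    threshold: float = ALTERNANS_THRESHOLD,
) -> BifurcationResult:
    """Bifurcation scan: last-two-beat peak Ca2+ against pacing cycle length.

    Runs :func:`run_paced` at every PCL in ``pcl_grid`` (default 300-700 ms
    in 50-ms steps). With multiple ``seeds`` the per-PCL alternans flag is
    the majority vote across seeds (recommended: >= 5) and the stored peaks
    come from the first seed. ``onset_pcl`` is the smallest scanned PCL
    whose flag is False.
    """
    grid = np.asarray(DEFAULT_PCL_GRID if pcl_grid is None else pcl_grid, dtype=float)
    if grid.size == 0:
        raise InvalidParameterError("pcl_grid must be non-empty")
    template = protocol or PacingProtocol()
    seed_list = [p.seed] if seeds is None else list(seeds)
    all_flags = np.zeros((len(seed_list), len(grid)), dtype=bool)
    peaks = np.zeros((len(grid), 2))
    for si, seed in enumerate(seed_list):
        for gi, pcl in enumerate(grid):
            proto = dataclasses.replace(template, pcl=float(pcl))
            try:
                trace = run_paced(p, proto, seed=int(seed))
            except IntegrationFailureError as exc:  # keep scanning other PCLs
                warnings.warn(f"PCL {pcl} ms failed: {exc}", stacklevel=2)
                all_flags[si, gi] = False
                continue
            _, flag = detect_alternans(trace.beat_peaks, threshold)
            all_flags[si, gi] = flag
            if si == 0:
                peaks[gi] = trace.beat_peaks[-2:]
    votes = all_flags.mean(axis=0)
    flags = votes > 0.5
    no_alt = grid[~flags]
    onset = float(no_alt.min()) if len(no_alt) else math.nan
    return BifurcationResult(
        pcl_values=grid,
        peaks=peaks,
        alternans_flags=flags,
        onset_pcl=onset,
        threshold=threshold,
        per_seed_flags=all_flags,
    )


def check_conservation(trace: SimTrace, p: SimParams | None = None) -> float:
    """Max relative drift of total Ca2+ over a closed-cell run."""
    m = trace.total_ca
    if len(m) == 0:
        return 0.0
    return float(np.max(np.abs(m - m[0])) / m[0])
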