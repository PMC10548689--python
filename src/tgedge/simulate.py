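"""Forward simulator of fluorogenic thrombin-generation plate data.

The simulator produces plate-reader fluorescence time series together with
the underlying ground truth, so that every downstream correction stage can
be tested against known free-thrombin trajectories.  The model has three
layers:

1. **Thrombin kinetics** -- free thrombin T(t) is driven by a
   phenomenological gamma-shaped prothrombinase pulse and removed by
   antithrombin (first order, modulated by the residual antithrombin
   fraction and heparin) and by alpha2-macroglobulin capture:

       dT/dt     = g(t) - (k_at * at_fraction * heparin_factor + k_a2m) T
       da2MT/dt  = k_a2m * T

   The amidolytic (substrate-cleaving) activity seen by the fluorogenic
   substrate is E(t) = T + f * a2MT, because the alpha2M-bound complex
   retains part of its small-substrate activity while being inert toward
   clotting factors -- this is the source of the sloped fluorescence tail.

2. **Substrate consumption** -- Michaelis-Menten cleavage of the ZGGR-AMC
   substrate, dS/dt = -kcat * (E/1000) * S / (Km + S) (E in nM, S in uM),
   integrated exactly through the implicit form
   Km*ln(S0/S) + (S0 - S) = (kcat/1000) * int E dt.

3. **Optics** -- released AMC plus any pre-spiked AMC forms the
   fluorophore load x(t); the inner filter effect (IFE) is modeled by the
   saturating transform Phi(x) = K (1 - exp(-x/K)), which is strictly
   increasing, concave, has unit slope at the origin, and tends to the
   identity as K -> infinity.  Uncleaved ZGGR-AFC substrate adds a
   constant bleed-through baseline in the AMC channel.  Gaussian read
   noise is seed-controlled.

Calibrator wells run the same substrate/optics pipeline with a constant
amidolytic activity E_cal (the thrombin--alpha2M calibrator reagent).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.signal import lfilter

from .plate import ConditionMeta, Plate, Well, ROLE_CALIBRATOR, ROLE_SAMPLE

__all__ = [
    "KineticParams",
    "OpticsParams",
    "GroundTruth",
    "ife_transform",
    "simulate_free_thrombin",
    "simulate_fluorescence",
    "make_calibrator_well",
    "generate_plate",
    "spike_preconsumption_percent",
    "SCENARIOS",
]

# Trigger-dose scaling: the drive amplitude grows log-linearly with the
# tissue-factor dose around a 5 pM reference, and the onset is delayed
# inversely with dose.
TF_REF_PM = 5.0
TF_LOG_SLOPE = 0.35
TF_DELAY_COEFF = 3.0  # pM * min
TF_SCALE_FLOOR = 0.02

# Severe FVIII deficiency scales the drive down and stretches it out.
FVIII_AMPLITUDE_FLOOR = 0.15
FVIII_TAU_STRETCH = 1.0

_REFINE = 20  # internal sub-steps per recorded interval


@dataclass
class KineticParams:
    """Plasma thrombin-generation kinetics.

    gen_amplitude : peak prothrombinase drive, nM thrombin/min
    gen_tau       : pulse time constant, min
    gen_shape     : pulse shape exponent (dimensionless)
    k_at          : antithrombin-mediated decay rate at normal AT, 1/min
    at_fraction   : residual antithrombin level, fraction of normal [0, 1]
    heparin_factor: multiplier on k_at when heparin is present (>= 1)
    k_a2m         : alpha2-macroglobulin capture rate, 1/min
    a2m_amidolytic_fraction : small-substrate activity retained by the
        alpha2M-thrombin complex, fraction [0, 1]
    tf_pM         : tissue-factor trigger dose, pM
    """

    gen_amplitude: float = 350.0
    gen_tau: float = 1.5
    gen_shape: float = 3.0
    k_at: float = 0.75
    at_fraction: float = 1.0
    heparin_factor: float = 1.0
    k_a2m: float = 0.035
    a2m_amidolytic_fraction: float = 0.55
    tf_pM: float = 5.0

    def validate(self) -> None:
        vals = [
            self.gen_amplitude,
            self.gen_tau,
            self.gen_shape,
            self.k_at,
            self.at_fraction,
            self.heparin_factor,
            self.k_a2m,
            self.a2m_amidolytic_fraction,
            self.tf_pM,
        ]
        if not np.isfinite(vals).all():
            raise ValueError("non-finite kinetic parameter")
        if min(self.gen_amplitude, self.k_at, self.k_a2m, self.tf_pM) < 0:
            raise ValueError("rates and amplitudes must be >= 0")
        if not (0.0 <= self.at_fraction <= 1.0):
            raise ValueError("at_fraction must lie in [0, 1]")
        if not (0.0 <= self.a2m_amidolytic_fraction <= 1.0):
            raise ValueError("a2m_amidolytic_fraction must lie in [0, 1]")
        if self.gen_tau <= 0:
            raise ValueError("gen_tau must be > 0")
        if self.heparin_factor < 1.0:
            raise ValueError("heparin_factor must be >= 1")

    def with_(self, **kwargs) -> "KineticParams":
        return replace(self, **kwargs)


@dataclass
class OpticsParams:
    """Detector and fluorophore optics.

    gain           : RFU per uM cleaved fluorophore in the linear limit
    ife_K          : IFE saturation constant, uM fluorophore-equivalent
                     (None or inf disables the IFE)
    dark_offset    : RFU
    noise_sd       : additive Gaussian read noise, RFU
    afc_bleed_coeff: RFU per uM of AFC-substrate equivalent bleeding into
                     the AMC channel
    early_drop_rfu : amplitude of the optional early-minutes baseline
                     transient (settling artifact), RFU; 0 disables
    early_drop_tau : transient time constant, min
    """

    gain: float = 20.0
    ife_K: float | None = 350.0
    dark_offset: float = 50.0
    noise_sd: float = 1.0
    afc_bleed_coeff: float = 2.0
    early_drop_rfu: float = 0.0
    early_drop_tau: float = 1.5

    def validate(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be > 0")
        if self.ife_K is not None and self.ife_K <= 0:
            raise ValueError("ife_K must be > 0 (or None for no IFE)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.afc_bleed_coeff < 0:
            raise ValueError("afc_bleed_coeff must be >= 0")
        if self.early_drop_tau <= 0:
            raise ValueError("early_drop_tau must be > 0")

    def with_(self, **kwargs) -> "OpticsParams":
        return replace(self, **kwargs)


@dataclass
class GroundTruth:
    """Simulator ground truth on the recording grid (times in minutes).

    free_thrombin and a2m_thrombin are nM; amidolytic is their weighted
    sum E = T + f * a2MT (nM); substrate and product are uM and satisfy
    S + P = S0 once the fluorescence stage has run.
    """

    times: np.ndarray
    free_thrombin: np.ndarray
    a2m_thrombin: np.ndarray
    amidolytic: np.ndarray
    substrate: np.ndarray | None = None
    product: np.ndarray | None = None
    # fine-grid internals (times, amidolytic) used for accurate substrate
    # integration; carried along but not part of the public contract
    fine: tuple[np.ndarray, np.ndarray] | None = None


def ife_transform(x: np.ndarray | float, ife_K: float | None) -> np.ndarray:
    """Saturating inner-filter transform Phi(x) = K (1 - exp(-x/K)).

    Phi is strictly increasing and concave with Phi'(0) = 1 and
    Phi(x) <= x; ife_K = None (or inf) gives the identity (no IFE).
    """
    x = np.asarray(x, dtype=float)
    if ife_K is None or not np.isfinite(ife_K):
        return x.copy()
    return -ife_K * np.expm1(-x / ife_K)


def ife_inverse(y: np.ndarray | float, ife_K: float | None) -> np.ndarray:
    """Inverse of :func:`ife_transform` (y must be < ife_K)."""
    y = np.asarray(y, dtype=float)
    if ife_K is None or not np.isfinite(ife_K):
        return y.copy()
    return -ife_K * np.log1p(-y / ife_K)


def _fine_grid(times: np.ndarray, refine: int = _REFINE) -> np.ndarray:
    n = times.size
    out = np.empty((n - 1) * refine + 1)
    for i in range(n - 1):
        out[i * refine : (i + 1) * refine] = np.linspace(
            times[i], times[i + 1], refine, endpoint=False
        )
    out[-1] = times[-1]
    return out


def _drive(kinetics: KineticParams, condition: ConditionMeta,
           t: np.ndarray) -> np.ndarray:
    """Prothrombinase drive g(t), nM thrombin/min, on grid t."""
    k = kinetics
    fv = min(max(condition.fviii_level, 0.0), 1.0)
    amp_scale = FVIII_AMPLITUDE_FLOOR + (1.0 - FVIII_AMPLITUDE_FLOOR) * fv
    tau = k.gen_tau * (1.0 + FVIII_TAU_STRETCH * (1.0 - fv))
    if k.tf_pM > 0:
        tf_scale = max(
            TF_SCALE_FLOOR, 1.0 + TF_LOG_SLOPE * math.log(k.tf_pM / TF_REF_PM)
        )
        delay = TF_DELAY_COEFF / k.tf_pM
    else:
        tf_scale = 0.0
        delay = 0.0
    amp = k.gen_amplitude * amp_scale * tf_scale
    u = np.maximum(t - delay, 0.0) / tau
    s = k.gen_shape
    # normalize the pulse so its maximum equals amp
    peak = s**s * math.exp(-s) if s > 0 else 1.0
    if s == 0:
        return np.where(u >= 0, amp * np.exp(-u), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = amp * np.where(u > 0, u**s * np.exp(-u), 0.0) / peak
    return g


def integrate_first_order(
    g: np.ndarray, delta: float, k: float
) -> np.ndarray:
    """Solve dT/dt = g(t) - k T, T(0)=0, on a uniform grid of step delta.

    Exponential integrator, exact when g is piecewise linear between
    grid nodes (hence exact for constant and linear drives).
    """
    if k > 0:
        alpha = math.exp(-k * delta)
        em1 = -math.expm1(-k * delta)  # 1 - e^{-k d}
        c2 = (delta / k - em1 / k**2) / delta
        c1 = em1 / k - c2
    else:
        alpha = 1.0
        c1 = c2 = delta / 2.0
    x = np.zeros_like(g)
    x[1:] = c1 * g[:-1] + c2 * g[1:]
    return lfilter([1.0], [1.0, -alpha], x)


def simulate_free_thrombin(
    kinetics: KineticParams, condition: ConditionMeta
) -> GroundTruth:
    """Solve the thrombin inhibition ODEs on the condition's time grid.

    Uses an exponential integrator that is exact for piecewise-linear
    drive, on a grid refined 20-fold relative to the recording cadence.
    """
    kinetics.validate()
    condition.validate()
    times = condition.time_grid()
    tf = _fine_grid(times)
    g = _drive(kinetics, condition, tf)
    k_tot = kinetics.k_at * kinetics.at_fraction * kinetics.heparin_factor \
        + kinetics.k_a2m
    delta = tf[1] - tf[0]
    T = np.maximum(integrate_first_order(g, delta, k_tot), 0.0)
    a2m = kinetics.k_a2m * cumulative_trapezoid(T, tf, initial=0.0)
    E = T + kinetics.a2m_amidolytic_fraction * a2m
    step = _REFINE
    return GroundTruth(
        times=times,
        free_thrombin=T[::step].copy(),
        a2m_thrombin=a2m[::step].copy(),
        amidolytic=E[::step].copy(),
        fine=(tf, E),
    )


def _solve_substrate(
    E_fine: np.ndarray,
    t_fine: np.ndarray,
    S0: float,
    kcat: float,
    Km: float,
) -> np.ndarray:
    """Integrate dS/dt = -kcat (E/1000) S/(Km+S) via the implicit form.

    Km ln(S0/S) + (S0 - S) = c(t) with c = (kcat/1000) int E dt, solved
    by a vectorized, monotone-safe Newton iteration.
    """
    if S0 == 0 or kcat == 0:
        return np.full_like(t_fine, S0, dtype=float)
    if Km <= 0:
        raise ValueError("Km must be > 0 when kcat > 0")
    c = (kcat / 1000.0) * cumulative_trapezoid(E_fine, t_fine, initial=0.0)
    # initial guess: first-order solution, always within (0, S0]
    S = S0 * np.exp(-c / (Km + S0))
    floor = S0 * 1e-14
    for _ in range(80):
        S = np.clip(S, floor, S0)
        f = Km * np.log(S0 / S) + (S0 - S) - c
        fp = -Km / S - 1.0
        step = f / fp
        S_new = np.clip(S - step, floor, S0)
        if np.max(np.abs(S_new - S)) < 1e-12 * S0:
            S = S_new
            break
        S = S_new
    return S


def simulate_fluorescence(
    truth: GroundTruth,
    optics: OpticsParams,
    condition: ConditionMeta,
    seed: int | None = 0,
    well_id: str = "S1",
    role: str = ROLE_SAMPLE,
    rng: np.random.Generator | None = None,
) -> Well:
    """Turn an amidolytic-activity trajectory into a fluorescence well.

    Consumes substrate according to Michaelis-Menten kinetics, applies
    the IFE transform to the fluorophore load (released product plus
    spiked AMC), adds the AFC bleed-through baseline and seeded Gaussian
    noise.  ``truth.substrate`` and ``truth.product`` are filled in
    place.
    """
    optics.validate()
    condition.validate()
    times = condition.time_grid()
    if truth.times.shape != times.shape or not np.allclose(
        truth.times, times, atol=1e-9
    ):
        raise ValueError("ground-truth grid does not match condition grid")
    if truth.fine is not None:
        t_fine, E_fine = truth.fine
    else:
        t_fine = _fine_grid(times)
        E_fine = np.interp(t_fine, truth.times, truth.amidolytic)
    S_fine = _solve_substrate(
        E_fine, t_fine, condition.substrate_total, condition.kcat,
        condition.Km,
    )
    S = S_fine[:: _REFINE]
    truth.substrate = S.copy()
    truth.product = condition.substrate_total - S
    x = truth.product + condition.amc_spike
    F = (
        optics.dark_offset
        + optics.gain * ife_transform(x, optics.ife_K)
        + optics.afc_bleed_coeff * condition.afc_substrate
    )
    if optics.early_drop_rfu:
        F = F + optics.early_drop_rfu * np.exp(-times / optics.early_drop_tau)
    if optics.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(seed)
        F = F + rng.normal(0.0, optics.noise_sd, size=F.shape)
    return Well(well_id=well_id, role=role, condition=condition,
                times=times, rfu=F)


def make_calibrator_well(
    optics: OpticsParams,
    condition: ConditionMeta,
    seed: int | None = 0,
    well_id: str = "C1",
    rng: np.random.Generator | None = None,
) -> tuple[Well, GroundTruth]:
    """Simulate a calibrator well with constant amidolytic activity E_cal.

    The calibrator reagent is a thrombin--alpha2M complex: it cleaves the
    substrate at a fixed rate but generates no thrombin burst of its own.
    """
    condition.validate()
    e_cal = condition.calibrator_activity
    if e_cal <= 0:
        raise ValueError("calibrator_activity must be > 0")
    times = condition.time_grid()
    t_fine = _fine_grid(times)
    truth = GroundTruth(
        times=times,
        free_thrombin=np.zeros_like(times),
        a2m_thrombin=np.zeros_like(times),
        amidolytic=np.full_like(times, e_cal),
        fine=(t_fine, np.full_like(t_fine, e_cal)),
    )
    well = simulate_fluorescence(
        truth, optics, condition, seed=seed, well_id=well_id,
        role=ROLE_CALIBRATOR, rng=rng,
    )
    return well, truth


# ---------------------------------------------------------------------------
# plate-level scenario generation


def spike_preconsumption_percent(
    amc_spike: float, substrate_total: float = 416.0
) -> float:
    """Express a free-AMC spike as a percent pre-consumption of substrate.

    A spike of x uM free fluorophore raises the baseline as if x uM of
    the S0 uM substrate had already been cleaved, i.e. 100 * x / S0.
    """
    if substrate_total <= 0:
        raise ValueError("substrate_total must be > 0")
    return 100.0 * amc_spike / substrate_total


def _well_coords(n: int) -> list[str]:
    rows = "ABCDEFGHIJKLMNOPQRSTUVWX"
    out = []
    for i in range(n):
        r, c = divmod(i, 12)
        if r >= len(rows):
            raise ValueError("plate too large (>288 wells)")
        out.append(f"{rows[r]}{c + 1}")
    return out


def _conditions_ife_spike(params: dict, base: ConditionMeta,
                          kin: KineticParams):
    spikes = params.get("amc_spikes", [0.0, 47.0, 70.0, 102.0, 200.0])
    fviii = params.get("fviii_levels", [0.0, 1.0])
    out = []
    for f in fviii:
        for s in spikes:
            label = f"spike{s:g}_fviii{f:g}"
            out.append((base.with_(amc_spike=float(s), fviii_level=float(f),
                                   label=label), kin))
    return out


def _conditions_substrate_reduction(params: dict, base: ConditionMeta,
                                    kin: KineticParams):
    # default: down 20-fold from the commercial concentration
    s0s = params.get(
        "substrate_totals", [416.0, 208.0, 104.0, 41.6, 20.8]
    )
    fviii = params.get("fviii_levels", [0.0, 1.0])
    out = []
    for f in fviii:
        for s0 in s0s:
            label = f"s0{s0:g}_fviii{f:g}"
            out.append((base.with_(substrate_total=float(s0),
                                   fviii_level=float(f), label=label), kin))
    return out


def _conditions_amc_afc_mixture(params: dict, base: ConditionMeta,
                                kin: KineticParams):
    total = params.get("total_substrate", 800.0)
    amc = params.get("amc_totals", [800.0, 600.0, 400.0, 200.0, 100.0])
    fviii = params.get("fviii_levels", [0.0, 1.0])
    out = []
    for f in fviii:
        for a in amc:
            if a > total:
                raise ValueError("AMC substrate exceeds the mixture total")
            label = f"amc{a:g}_fviii{f:g}"
            cond = base.with_(
                substrate_total=float(a),
                afc_substrate=float(total - a),
                fviii_level=float(f),
                label=label,
            )
            out.append((cond, kin))
    return out


def _conditions_atiii(params: dict, base: ConditionMeta, kin: KineticParams):
    tfs = params.get("tf_pM", [0.12, 0.6, 2.6, 10.0, 20.0])
    heparin = params.get("heparin", [False, True])
    at_fraction = params.get("at_fraction", 0.05)
    hep_factor = params.get("heparin_factor", 3.0)
    base = base.with_(substrate_total=params.get("substrate_total", 800.0))
    out = []
    for h in heparin:
        for tf in tfs:
            label = f"tf{tf:g}_hep{int(bool(h))}"
            k = kin.with_(
                tf_pM=float(tf),
                at_fraction=float(at_fraction),
                heparin_factor=float(hep_factor) if h else 1.0,
            )
            out.append((base.with_(label=label), k))
    return out


def _conditions_custom(params: dict, base: ConditionMeta,
                       kin: KineticParams):
    conds = params.get("conditions")
    if not conds:
        raise ValueError("custom scenario requires a 'conditions' list")
    out = []
    for i, spec in enumerate(conds):
        cond_over = dict(spec.get("condition", {}))
        kin_over = dict(spec.get("kinetics", {}))
        label = spec.get("label", cond_over.get("label", f"cond{i}"))
        cond_over["label"] = label
        out.append((base.with_(**cond_over), kin.with_(**kin_over)))
    return out


SCENARIOS = {
    "ife_spike": _conditions_ife_spike,
    "substrate_reduction": _conditions_substrate_reduction,
    "amc_afc_mixture": _conditions_amc_afc_mixture,
    "atiii_procoagulant": _conditions_atiii,
    "custom": _conditions_custom,
}


def generate_plate(scenario: dict, seed: int = 0) -> Plate:
    """Simulate a full plate from a structured scenario configuration.

    ``scenario`` is a key tree with blocks::

        scenario: one of ife_spike | substrate_reduction |
                  amc_afc_mixture | atiii_procoagulant | custom
        kinetics: {field: value, ...}     # KineticParams overrides
        optics: {field: value, ...}       # OpticsParams overrides
        condition: {field: value, ...}    # base ConditionMeta overrides
        params: {...}                     # scenario-specific knobs
        replicates: int (>= 1, default 1)
        calibrator_replicates: int (>= 1, default 2)
        calibrator_spiked: bool (default false) -- whether calibrator
            wells carry the sample's free-AMC spike

    Calibrator wells always share the sample condition's substrate and
    AFC state; by default they do not carry the free-AMC spike, which is
    a property of the plasma aliquot being interrogated.  Deterministic
    for a fixed seed.
    """
    cfg = dict(scenario)
    name = cfg.get("scenario", cfg.get("name"))
    if name not in SCENARIOS:
        raise ValueError(
            f"unknown scenario {name!r}; expected one of {sorted(SCENARIOS)}"
        )
    base_cond = ConditionMeta(**cfg.get("condition", {}))
    kin = KineticParams(**cfg.get("kinetics", {}))
    optics = OpticsParams(**cfg.get("optics", {}))
    replicates = int(cfg.get("replicates", 1))
    cal_replicates = int(cfg.get("calibrator_replicates", 2))
    cal_spiked = bool(cfg.get("calibrator_spiked", False))
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if cal_replicates < 1:
        raise ValueError("each condition needs >= 1 calibrator well")
    conditions = SCENARIOS[name](cfg.get("params", {}), base_cond, kin)

    n_wells = len(conditions) * (replicates + cal_replicates)
    coords = _well_coords(n_wells)
    rng = np.random.default_rng(seed)
    plate = Plate(meta={"scenario": name, "seed": int(seed),
                        "instrument": "tgedge-simulator", "channel": "AMC"})
    idx = 0
    for cond, ckin in conditions:
        truth = simulate_free_thrombin(ckin, cond)
        for _ in range(replicates):
            wid = coords[idx]
            idx += 1
            # each replicate re-draws noise from the shared stream; copy
            # the truth so every well keeps its own substrate trajectory
            t = GroundTruth(
                times=truth.times,
                free_thrombin=truth.free_thrombin.copy(),
                a2m_thrombin=truth.a2m_thrombin.copy(),
                amidolytic=truth.amidolytic.copy(),
                fine=truth.fine,
            )
            w = simulate_fluorescence(
                t, optics, cond, well_id=wid, rng=rng
            )
            plate.wells.append(w)
            plate.truth[wid] = t
        cal_cond = cond if cal_spiked else cond.with_(amc_spike=0.0)
        cal_ids = []
        for _ in range(cal_replicates):
            wid = coords[idx]
            idx += 1
            cw, ct = make_calibrator_well(
                optics, cal_cond, well_id=wid, rng=rng
            )
            plate.wells.append(cw)
            plate.truth[wid] = ct
            cal_ids.append(wid)
        plate.pairing[cond.label] = cal_ids
    plate.validate()
    return plate
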