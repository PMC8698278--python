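"""Replica exchange with solute scaling (REST2).

Instead of heating whole replicas, REST2 scales the solute Hamiltonian:
rung m runs at the common bath temperature T0 with solute–solute energy
multiplied by λ_m = T0/T_m and solute–solvent energy by √λ_m, so the
solute at rung m effectively experiences temperature T_m.  For the
solvent-free Gō surrogate (e_pw = e_ww = 0) the effective temperature
is exactly T0/λ; the mean-field energy-matching estimate is provided
for generality.

The exchange criterion between rungs a and b holding conformations
X_a, X_b is

    Δ = β0·[(λa − λb)·(E_pp(X_b) − E_pp(X_a))
            + (√λa − √λb)·(E_pw(X_b) − E_pw(X_a))]

accepted with probability min(1, e^−Δ); on acceptance the
conformations (with their energies) swap rungs while replica identity
follows the conformation.  Exchange phases alternate between even
(0–1, 2–3, ...) and odd (1–2, 3–4, ...) adjacent pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .go_model import Conformation, GoParameters, GoSystem, _full_energy, _run_mc
from .structure_io import ContactMap

__all__ = [
    "LadderSpec",
    "ExchangeAttempt",
    "ReplicaEnsemble",
    "EffectiveTemperatureMap",
    "build_ladder",
    "tune_ladder",
    "count_round_trips",
    "two_state_toy_occupancies",
    "scaled_energy",
    "attempt_exchange",
    "run_rest2",
    "Rest2History",
    "effective_temperature",
]


@dataclass(frozen=True)
class LadderSpec:
    """Solute-temperature ladder and the equivalent λ scaling factors."""

    t0: float
    solute_temperatures: np.ndarray  # K, ascending, first == t0
    lambdas: np.ndarray              # t0 / solute_temperatures, decreasing

    def __post_init__(self) -> None:
        ts = np.asarray(self.solute_temperatures, dtype=float)
        lams = np.asarray(self.lambdas, dtype=float)
        object.__setattr__(self, "solute_temperatures", ts)
        object.__setattr__(self, "lambdas", lams)
        if len(ts) != len(lams):
            raise ValueError("temperature and lambda lists differ in length")
        if abs(ts[0] - self.t0) > 1e-9:
            raise ValueError("first solute temperature must equal t0")
        if np.any(np.diff(lams) >= 0):
            raise ValueError("lambdas must be strictly decreasing")
        if np.any(lams <= 0) or np.any(lams > 1.0 + 1e-12):
            raise ValueError("lambdas must lie in (0, 1]")

    def __len__(self) -> int:
        return len(self.lambdas)


def build_ladder(t0: float, t_max: float, n_rungs: int) -> LadderSpec:
    """Geometrically spaced solute temperatures t0 → t_max."""
    if t_max <= t0:
        raise ValueError("t_max must exceed t0")
    if n_rungs < 2:
        raise ValueError("need at least 2 rungs")
    m = np.arange(n_rungs)
    ts = t0 * (t_max / t0) ** (m / (n_rungs - 1))
    return LadderSpec(t0=t0, solute_temperatures=ts, lambdas=t0 / ts)


def scaled_energy(e_pp: float, e_pw: float, e_ww: float, lam: float) -> float:
    """REST2-scaled potential energy λ·E_pp + √λ·E_pw + E_ww."""
    if not (0.0 < lam <= 1.0):
        raise ValueError("lam must be in (0, 1]")
    return lam * e_pp + math.sqrt(lam) * e_pw + e_ww


@dataclass
class ExchangeAttempt:
    sweep: int
    rung_a: int
    rung_b: int
    delta: float
    accepted: bool


@dataclass
class ReplicaEnsemble:
    """Live state of a REST2 run: one conformation per rung, with its
    decomposed solute energies, plus the exchange log and RNG."""

    ladder: LadderSpec
    conformations: list[Conformation]
    replica_ids: np.ndarray
    e_pp: np.ndarray
    e_pw: np.ndarray
    e_ww: np.ndarray
    rng: np.random.Generator
    exchange_log: list[ExchangeAttempt] = field(default_factory=list)
    sweep: int = 0

    def __post_init__(self) -> None:
        m = len(self.ladder)
        if not (len(self.conformations) == len(self.replica_ids) == len(self.e_pp) == m):
            raise ValueError("ensemble arrays must all have one entry per rung")


def attempt_exchange(ensemble: ReplicaEnsemble, rung_a: int, rung_b: int, beta0: float) -> bool:
    """One Metropolis swap attempt between two rungs; logged either way."""
    if rung_a == rung_b:
        raise ValueError("identical rung indices")
    lam = ensemble.ladder.lambdas
    la, lb = lam[rung_a], lam[rung_b]
    d_pp = ensemble.e_pp[rung_b] - ensemble.e_pp[rung_a]
    d_pw = ensemble.e_pw[rung_b] - ensemble.e_pw[rung_a]
    delta = beta0 * ((la - lb) * d_pp + (math.sqrt(la) - math.sqrt(lb)) * d_pw)
    accepted = delta <= 0.0 or ensemble.rng.random() < math.exp(-delta)
    if accepted:
        for arr in (ensemble.e_pp, ensemble.e_pw, ensemble.e_ww, ensemble.replica_ids):
            arr[rung_a], arr[rung_b] = arr[rung_b], arr[rung_a]
        ensemble.conformations[rung_a], ensemble.conformations[rung_b] = (
            ensemble.conformations[rung_b],
            ensemble.conformations[rung_a],
        )
    ensemble.exchange_log.append(
        ExchangeAttempt(ensemble.sweep, rung_a, rung_b, float(delta), bool(accepted))
    )
    return bool(accepted)


@dataclass
class Rest2History:
    """Per-rung time series and bookkeeping of a REST2 run.

    ``e_pp`` and ``replica_id`` are sampled at every exchange interval;
    ``rec_coords`` holds conformations thinned to ``record_every``
    sweeps (axis order rung, frame, residue, xyz).
    """

    ladder: LadderSpec
    sample_sweeps: np.ndarray          # (S,)
    e_pp: np.ndarray                   # (M, S)
    replica_id: np.ndarray             # (M, S) int
    rec_sweeps: np.ndarray             # (F,)
    rec_coords: np.ndarray             # (M, F, N, 3)
    pair_acceptance: np.ndarray        # (M-1,) mean acceptance per adjacent pair
    ensemble: ReplicaEnsemble

    @property
    def mean_acceptance(self) -> float:
        return float(np.mean(self.pair_acceptance))


def run_rest2(
    cmap: ContactMap,
    params: GoParameters,
    initial: Conformation,
    ladder: LadderSpec,
    n_sweeps: int,
    exchange_interval: int = 10,
    seed: int = 0,
    record_every: int = 50,
    native_coordinates: np.ndarray | None = None,
    initial_per_rung: list[Conformation] | None = None,
) -> Rest2History:
    """Drive the full REST2 scheme on the Gō surrogate.

    Every rung starts from ``initial`` (or its entry in
    ``initial_per_rung`` when given, e.g. to warm-start from a previous
    run) and is propagated at the base temperature with its λ-scaled
    Hamiltonian; exchanges are attempted every ``exchange_interval``
    sweeps, alternating even/odd adjacent pairs.  One master seed spawns
    independent per-rung move streams and one exchange stream, so runs
    are reproducible bit-for-bit.
    """
    if exchange_interval < 1:
        raise ValueError("exchange_interval must be >= 1")
    if record_every % exchange_interval != 0:
        raise ValueError("record_every must be a multiple of exchange_interval")
    m = len(ladder)
    n_segments = n_sweeps // exchange_interval
    system = GoSystem.from_contact_map(cmap, params, native_coordinates=native_coordinates)
    beta0 = 1.0 / (params.kB * ladder.t0)

    root = np.random.SeedSequence(seed)
    seed_rungs, seed_exch = root.spawn(2)
    move_seeds = np.random.Generator(np.random.PCG64(seed_rungs)).integers(
        0, 2**32, size=(m, max(n_segments, 1)), dtype=np.uint64
    )
    exch_rng = np.random.Generator(np.random.PCG64(seed_exch))

    if initial_per_rung is not None:
        if len(initial_per_rung) != m:
            raise ValueError("initial_per_rung must have one conformation per rung")
        coords = [np.ascontiguousarray(c.coordinates, dtype=float).copy() for c in initial_per_rung]
    else:
        coords = [np.ascontiguousarray(initial.coordinates, dtype=float).copy() for _ in range(m)]

    def full_epp(x: np.ndarray) -> float:
        e_nat, e_bond, e_exc = _full_energy(
            x, system.nat_mask, system.nat_r0, system.nat_w, system.b0,
            params.epsilon, params.bond_k, params.excluded_sigma,
            system.angle_k, system.cos_theta0,
        )
        return float(e_nat + e_bond + e_exc)

    ens = ReplicaEnsemble(
        ladder=ladder,
        conformations=[Conformation(c, 0) for c in coords],
        replica_ids=np.arange(m),
        e_pp=np.array([full_epp(c) for c in coords]),
        e_pw=np.zeros(m),
        e_ww=np.zeros(m),
        rng=exch_rng,
    )

    n_frames = n_sweeps // record_every + 1
    rec_coords = np.empty((m, n_frames, cmap.n_residues, 3))
    rec_sweeps = np.empty(n_frames, dtype=np.int64)
    for r in range(m):
        rec_coords[r, 0] = ens.conformations[r].coordinates
    rec_sweeps[0] = 0
    k_rec = 1

    sample_sweeps = np.empty(n_segments, dtype=np.int64)
    e_pp_hist = np.empty((m, n_segments))
    replica_hist = np.empty((m, n_segments), dtype=np.int64)

    for seg in range(n_segments):
        sweep_end = (seg + 1) * exchange_interval
        for r in range(m):
            x = np.ascontiguousarray(ens.conformations[r].coordinates).copy()
            rec, _, _ = _run_mc(
                x, exchange_interval, exchange_interval, beta0 * ladder.lambdas[r],
                params.step_sigma, params.crank_max_angle,
                system.nat_mask, system.nat_r0, system.nat_w, system.b0,
                params.epsilon, params.bond_k, params.excluded_sigma,
                system.angle_k, system.cos_theta0,
                np.uint32(move_seeds[r, seg] & 0xFFFFFFFF),
            )
            ens.conformations[r] = Conformation(rec[-1].copy(), sweep_end)
            ens.e_pp[r] = full_epp(rec[-1])
        ens.sweep = sweep_end
        # alternate even (0-1, 2-3, ...) and odd (1-2, 3-4, ...) phases
        start = 0 if seg % 2 == 0 else 1
        for a in range(start, m - 1, 2):
            attempt_exchange(ens, a, a + 1, beta0)
        sample_sweeps[seg] = sweep_end
        e_pp_hist[:, seg] = ens.e_pp
        replica_hist[:, seg] = ens.replica_ids
        if sweep_end % record_every == 0 and k_rec < n_frames:
            for r in range(m):
                rec_coords[r, k_rec] = ens.conformations[r].coordinates
            rec_sweeps[k_rec] = sweep_end
            k_rec += 1

    pair_acc = np.zeros(max(m - 1, 0))
    for a in range(m - 1):
        attempts = [e.accepted for e in ens.exchange_log if e.rung_a == a and e.rung_b == a + 1]
        pair_acc[a] = np.mean(attempts) if attempts else np.nan
    return Rest2History(
        ladder=ladder,
        sample_sweeps=sample_sweeps,
        e_pp=e_pp_hist,
        replica_id=replica_hist,
        rec_sweeps=rec_sweeps[:k_rec],
        rec_coords=rec_coords[:, :k_rec],
        pair_acceptance=pair_acc,
        ensemble=ens,
    )


def tune_ladder(
    cmap: ContactMap,
    params: GoParameters,
    initial: Conformation,
    t0: float,
    t_max: float,
    n_rungs: int,
    seed: int = 0,
    pilot_sweeps: int = 30_000,
    n_iterations: int = 3,
    exchange_interval: int = 10,
    native_coordinates: np.ndarray | None = None,
) -> LadderSpec:
    """Acceptance-equalising ladder between fixed endpoints.

    Geometric spacing concentrates no rungs where the heat capacity
    peaks, so the pair straddling a cooperative transition becomes the
    exchange bottleneck.  Starting from the geometric ladder, short
    pilot runs measure per-pair acceptance; rung temperatures are then
    redistributed in ln T so that the estimated "difficulty"
    −ln(acceptance) accumulates equally between consecutive rungs
    (endpoints stay fixed).  Two iterations are usually enough to lift
    the worst pair close to the ladder average.  Deterministic per seed.
    """
    ladder = build_ladder(t0, t_max, n_rungs)
    warm: list[Conformation] | None = None
    for it in range(n_iterations):
        hist = run_rest2(
            cmap, params, initial, ladder, n_sweeps=pilot_sweeps,
            exchange_interval=exchange_interval, seed=seed + it,
            record_every=pilot_sweeps, native_coordinates=native_coordinates,
            initial_per_rung=warm,
        )
        acc = np.clip(np.nan_to_num(hist.pair_acceptance, nan=0.0), 1e-3, 1.0 - 1e-6)
        difficulty = -np.log(acc)
        cum = np.concatenate([[0.0], np.cumsum(difficulty)])
        targets = np.linspace(0.0, cum[-1], n_rungs)
        log_t = np.log(ladder.solute_temperatures)
        new_log_t = np.interp(targets, cum, log_t)
        ts = np.exp(new_log_t)
        ts[0], ts[-1] = t0, t_max
        ts = np.maximum.accumulate(ts + np.arange(n_rungs) * 1e-9)  # keep strictly ascending
        old_ts = ladder.solute_temperatures
        ladder = LadderSpec(t0=t0, solute_temperatures=ts, lambdas=t0 / ts)
        # warm-start the next pilot from the nearest old rung's final
        # conformation, so the transition region is properly developed
        # by the time its acceptance is measured
        warm = [
            hist.ensemble.conformations[int(np.argmin(np.abs(old_ts - t)))] for t in ts
        ]
    return ladder


def count_round_trips(replica_id_history: np.ndarray) -> int:
    """Total bottom→top→bottom round trips over all replicas.

    ``replica_id_history`` has shape (rungs, samples): entry [m, s] is
    the replica occupying rung m at sample s.  Healthy REST2 runs show
    nonzero replica traffic between the end rungs.
    """
    hist = np.asarray(replica_id_history)
    m, s = hist.shape
    trips = 0
    for rid in range(int(hist.max()) + 1):
        pos = np.argmax(hist == rid, axis=0)
        phase = 0  # 0: waiting for bottom, 1: climbing, 2: returned
        for p in pos:
            if phase == 0 and p == 0:
                phase = 1
            elif phase == 1 and p == m - 1:
                phase = 2
            elif phase == 2 and p == 0:
                trips += 1
                phase = 1
    return trips


def two_state_toy_occupancies(
    ladder: LadderSpec,
    barrier_energy: float,
    n_steps: int,
    seed: int,
    beta0: float | None = None,
    kB: float = 0.0083145,
) -> tuple[np.ndarray, np.ndarray]:
    """Validation toy: REST2 on a two-level system.

    Each rung holds a particle with two enumerable states of solute
    energy 0 and ``barrier_energy`` (kJ/mol).  Per step every rung
    attempts one Metropolis flip under its λ-scaled Hamiltonian, then
    adjacent rungs exchange through :func:`attempt_exchange` (even/odd
    alternation).  Returns (observed, exact) occupancies of the excited
    state per rung; exact is the λ-scaled Boltzmann weight
    e^{−β0·λ·E} / (1 + e^{−β0·λ·E}).  Used to verify detailed balance
    of the full exchange scheme.
    """
    m = len(ladder)
    if beta0 is None:
        beta0 = 1.0 / (kB * ladder.t0)
    rng = np.random.default_rng(seed)
    states = np.zeros(m, dtype=int)
    ens = ReplicaEnsemble(
        ladder=ladder,
        conformations=[Conformation(np.zeros((1, 3))) for _ in range(m)],
        replica_ids=np.arange(m),
        e_pp=np.zeros(m),
        e_pw=np.zeros(m),
        e_ww=np.zeros(m),
        rng=np.random.default_rng(rng.integers(2**31)),
    )
    counts = np.zeros(m)
    for step in range(n_steps):
        for r in range(m):
            de = barrier_energy if states[r] == 0 else -barrier_energy
            if de <= 0 or rng.random() < math.exp(-beta0 * ladder.lambdas[r] * de):
                states[r] = 1 - states[r]
                ens.e_pp[r] = barrier_energy * states[r]
        start = step % 2
        for a in range(start, m - 1, 2):
            if attempt_exchange(ens, a, a + 1, beta0):
                states[a], states[a + 1] = states[a + 1], states[a]
        counts += states
    observed = counts / n_steps
    w = np.exp(-beta0 * ladder.lambdas * barrier_energy)
    return observed, w / (1.0 + w)


@dataclass(frozen=True)
class EffectiveTemperatureMap:
    """Per-rung temperature the solute effectively experiences."""

    teff: np.ndarray
    method: str

    def __post_init__(self) -> None:
        t = np.asarray(self.teff, dtype=float)
        object.__setattr__(self, "teff", t)
        if np.any(np.diff(t) < -1e-9):
            raise ValueError("Teff must be non-decreasing along the ladder")


def effective_temperature(
    ladder: LadderSpec,
    method: str = "analytic",
    reference_series: tuple[np.ndarray, np.ndarray] | None = None,
    rung_mean_epp: np.ndarray | None = None,
) -> EffectiveTemperatureMap:
    """Map ladder rungs to effective temperatures.

    ``analytic`` — exact for a solvent-free solute: Teff = T0/λ.
    ``mean_field`` — energy matching: Teff of a rung is the temperature
    at which an unscaled reference scan (``reference_series`` =
    (temperatures, mean solute energies)) reaches that rung's observed
    mean solute energy (``rung_mean_epp``), by piecewise-linear
    interpolation.
    """
    if method == "analytic":
        return EffectiveTemperatureMap(teff=ladder.t0 / ladder.lambdas, method="analytic")
    if method != "mean_field":
        raise ValueError(f"unknown method {method!r}")
    if reference_series is None or rung_mean_epp is None:
        raise ValueError("mean_field requires reference_series and rung_mean_epp")
    t_scan, e_scan = (np.asarray(a, dtype=float) for a in reference_series)
    order = np.argsort(t_scan)
    t_scan, e_scan = t_scan[order], e_scan[order]
    if np.any(np.diff(e_scan) <= 0):
        raise ValueError("reference mean energies must increase with temperature")
    teff = np.empty(len(ladder))
    for r, e in enumerate(np.asarray(rung_mean_epp, dtype=float)):
        if not (e_scan[0] <= e <= e_scan[-1]):
            raise ValueError(f"rung {r} mean energy {e:.3f} outside the scanned range")
        teff[r] = np.interp(e, e_scan, t_scan)
    teff[np.isclose(ladder.lambdas, 1.0)] = ladder.t0
    return EffectiveTemperatureMap(teff=teff, method="mean_field")
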