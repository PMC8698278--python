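"""Two-state thermodynamic fits of melting curves.

The observable Q_N(T) is modelled as a population-weighted average of a
folded and an unfolded baseline, each linear in temperature:

    Q_N(T) = f_F(T)·(qf0 + qf1·T) + (1 − f_F(T))·(qu0 + qu1·T)

with the folded fraction given by the two-state equilibrium

    f_F(T) = 1 / (1 + exp(−ΔG_u(T) / (R·T)))

and the unfolding free energy by the Gibbs–Helmholtz relation

    ΔG_u(T) = ΔH_vH·(1 − T/T_m) + ΔC_p·((T − T_m) − T·ln(T/T_m))

ΔC_p is fixed at 0 by default (near-sigmoidal curves rarely constrain
it).  R is the same constant as kB here because energies are per mole
(kJ/mol).  T_m is the temperature where f_F = 0.5, identically the fit
parameter.  ΔΔG_u between two variants at a stated temperature is the
difference of their ΔG_u(T); negative values mean the second variant
(the mutant) is destabilised.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .analysis import MeltingCurve
from .go_model import KB

R_GAS = KB  # kJ/mol/K, molar convention

__all__ = [
    "TwoStateFit",
    "StabilityComparison",
    "fit_two_state",
    "folded_fraction",
    "delta_delta_g",
    "load_melting_curve_tsv",
]


@dataclass(frozen=True)
class TwoStateFit:
    """Fitted two-state model: T_m, van 't Hoff enthalpy, baselines."""

    tm: float                 # K
    dh_vh: float              # kJ/mol at tm
    dcp: float                # kJ/mol/K
    baseline_folded: tuple[float, float]    # (qf0, qf1)
    baseline_unfolded: tuple[float, float]  # (qu0, qu1)
    covariance: np.ndarray    # over the free parameters, fit order
    param_names: tuple[str, ...]
    r_gas: float = R_GAS

    def dg_u(self, temperature: float | np.ndarray) -> float | np.ndarray:
        """Unfolding free energy ΔG_u(T), kJ/mol (Gibbs–Helmholtz)."""
        t = np.asarray(temperature, dtype=float)
        dg = self.dh_vh * (1.0 - t / self.tm)
        if self.dcp:
            dg = dg + self.dcp * ((t - self.tm) - t * np.log(t / self.tm))
        return dg if dg.ndim else float(dg)

    def dg_u_variance(self, temperature: float) -> float:
        """First-order variance of ΔG_u(T) from the fit covariance."""
        t = float(temperature)
        grad = np.zeros(len(self.param_names))
        idx = {n: k for k, n in enumerate(self.param_names)}
        grad[idx["tm"]] = self.dh_vh * t / self.tm**2
        if self.dcp:
            grad[idx["tm"]] += self.dcp * (t / self.tm - 1.0)
        grad[idx["dh_vh"]] = 1.0 - t / self.tm
        if "dcp" in idx:
            grad[idx["dcp"]] = (t - self.tm) - t * np.log(t / self.tm)
        return float(grad @ self.covariance @ grad)

    def predict_qn(self, temperature: float | np.ndarray) -> np.ndarray:
        t = np.asarray(temperature, dtype=float)
        ff = folded_fraction(self, t)
        qf = self.baseline_folded[0] + self.baseline_folded[1] * t
        qu = self.baseline_unfolded[0] + self.baseline_unfolded[1] * t
        return ff * qf + (1.0 - ff) * qu

    def to_dict(self) -> dict:
        return {
            "tm_K": self.tm,
            "dh_vh_kJ_mol": self.dh_vh,
            "dcp_kJ_mol_K": self.dcp,
            "baseline_folded": list(self.baseline_folded),
            "baseline_unfolded": list(self.baseline_unfolded),
            "param_names": list(self.param_names),
            "covariance": self.covariance.tolist(),
        }


def folded_fraction(fit: TwoStateFit, temperature: float | np.ndarray) -> float | np.ndarray:
    """f_F(T) = 1/(1 + exp(−ΔG_u(T)/(R·T))), strictly in (0, 1)."""
    t = np.asarray(temperature, dtype=float)
    if np.any(t <= 0):
        raise ValueError("temperature must be positive")
    out = 1.0 / (1.0 + np.exp(-np.asarray(fit.dg_u(t)) / (fit.r_gas * t)))
    return out if out.ndim else float(out)


def _model(theta: np.ndarray, t: np.ndarray, with_dcp: bool) -> np.ndarray:
    tm, dh, qf0, qf1, qu0, qu1 = theta[:6]
    dcp = theta[6] if with_dcp else 0.0
    dg = dh * (1.0 - t / tm) + dcp * ((t - tm) - t * np.log(t / tm))
    ff = 1.0 / (1.0 + np.exp(np.clip(-dg / (R_GAS * t), -500, 500)))
    return ff * (qf0 + qf1 * t) + (1.0 - ff) * (qu0 + qu1 * t)


def fit_two_state(curve: MeltingCurve, with_dcp: bool = False) -> TwoStateFit:
    """Weighted least-squares two-state fit of a melting curve.

    Weights are 1/sem; rungs reporting sem = 0 are assigned the median
    sem of the curve (equal weights when every sem is 0).  Initial T_m
    is the temperature where Q_N crosses the midpoint of its range;
    initial ΔH_vH comes from the slope there.
    """
    t = np.asarray(curve.teff, dtype=float)
    q = np.asarray(curve.qn_mean, dtype=float)
    sem = np.asarray(curve.qn_sem, dtype=float).copy()
    if len(t) < 6:
        raise ValueError("need at least 6 temperature points")
    if np.all(sem == 0):
        sem[:] = 1.0
    else:
        med = np.median(sem[sem > 0])
        sem[sem == 0] = med
    # initial guesses
    q_mid = 0.5 * (q.max() + q.min())
    k_mid = int(np.argmin(np.abs(q - q_mid)))
    tm0 = float(t[k_mid])
    slope = np.gradient(q, t)[k_mid]
    # for a pure sigmoid, dQ/dT at Tm = −ΔH·Δq/(4·R·Tm²)
    dq = max(q.max() - q.min(), 1e-3)
    dh0 = float(np.clip(-4.0 * R_GAS * tm0**2 * slope / dq, 10.0, 5000.0))
    theta0 = [tm0, dh0, q.max(), 0.0, q.min(), 0.0]
    names = ["tm", "dh_vh", "qf0", "qf1", "qu0", "qu1"]
    if with_dcp:
        theta0.append(0.0)
        names.append("dcp")

    def resid(theta: np.ndarray) -> np.ndarray:
        return (_model(theta, t, with_dcp) - q) / sem

    # baseline bounds keep the sigmoid identifiable on broad transitions:
    # intercepts within an expanded observable range, slopes gentle
    lo = [t.min() * 0.5, 1.0, -1.0, -0.01, -1.0, -0.01] + ([-np.inf] if with_dcp else [])
    hi = [t.max() * 2.0, np.inf, 2.0, 0.01, 2.0, 0.01] + ([np.inf] if with_dcp else [])
    sol = least_squares(resid, theta0, bounds=(lo, hi), method="trf", xtol=1e-12, ftol=1e-12)
    if not sol.success:
        raise RuntimeError(f"two-state fit did not converge: {sol.message}")
    tm = float(sol.x[0])
    if not (0.5 * t.min() <= tm <= 2.0 * t.max()):
        raise RuntimeError(
            f"fitted T_m {tm:.1f} K outside 0.5–2× the data range "
            f"[{t.min():.0f}, {t.max():.0f}] K; residual cost {sol.cost:.3g}"
        )
    # covariance from the Jacobian of the weighted residuals
    dof = max(len(t) - len(sol.x), 1)
    jtj = sol.jac.T @ sol.jac
    try:
        cov = np.linalg.inv(jtj) * 2.0 * sol.cost / dof
    except np.linalg.LinAlgError:
        cov = np.full((len(sol.x), len(sol.x)), np.nan)
    return TwoStateFit(
        tm=tm,
        dh_vh=float(sol.x[1]),
        dcp=float(sol.x[6]) if with_dcp else 0.0,
        baseline_folded=(float(sol.x[2]), float(sol.x[3])),
        baseline_unfolded=(float(sol.x[4]), float(sol.x[5])),
        covariance=cov,
        param_names=tuple(names),
    )


def fit_two_state_paired(
    curve_a: MeltingCurve, curve_b: MeltingCurve, share_dh: bool = False
) -> tuple[TwoStateFit, TwoStateFit]:
    """Joint two-state fit of two melting curves with shared baselines.

    When two variants are measured on the same observable (Q_N over a
    common native contact set), their folded and unfolded baselines are
    physically the same; fitting them jointly (parameters T_m and ΔH_vH
    per curve, one shared pair of linear baselines) removes the
    baseline/enthalpy trade-off that otherwise dominates the
    uncertainty of extrapolated ΔΔG_u.

    ``share_dh`` additionally ties the van 't Hoff enthalpy across the
    two curves — the parsimonious model when the perturbation is small
    relative to what the data can resolve (same spirit as fixing
    ΔC_p = 0); ΔΔG_u then reduces to ΔH·T·(T_m^b − T_m^a)/(T_m^a·T_m^b),
    the classic melting-shift estimate.
    """
    ta, qa, sa = curve_a.teff, curve_a.qn_mean, np.array(curve_a.qn_sem, dtype=float)
    tb, qb, sb = curve_b.teff, curve_b.qn_mean, np.array(curve_b.qn_sem, dtype=float)
    for s in (sa, sb):
        if np.all(s == 0):
            s[:] = 1.0
        else:
            s[s == 0] = np.median(s[s > 0])

    single_a = fit_two_state(curve_a)
    single_b = fit_two_state(curve_b)
    q_all = np.concatenate([qa, qb])
    base0 = [
        *(np.add(single_a.baseline_folded, single_b.baseline_folded) / 2),
        *(np.add(single_a.baseline_unfolded, single_b.baseline_unfolded) / 2),
    ]
    if share_dh:
        theta0 = np.array([single_a.tm, single_b.tm,
                           0.5 * (single_a.dh_vh + single_b.dh_vh), *base0])
    else:
        theta0 = np.array([single_a.tm, single_a.dh_vh,
                           single_b.tm, single_b.dh_vh, *base0])

    def unpack(theta):
        if share_dh:
            tm_a, tm_b, dh, qf0, qf1, qu0, qu1 = theta
            return tm_a, dh, tm_b, dh, (qf0, qf1, qu0, qu1)
        tm_a, dh_a, tm_b, dh_b, qf0, qf1, qu0, qu1 = theta
        return tm_a, dh_a, tm_b, dh_b, (qf0, qf1, qu0, qu1)

    def model(theta):
        tm_a, dh_a, tm_b, dh_b, (qf0, qf1, qu0, qu1) = unpack(theta)
        out = []
        for t, tm, dh in ((ta, tm_a, dh_a), (tb, tm_b, dh_b)):
            dg = dh * (1.0 - t / tm)
            ff = 1.0 / (1.0 + np.exp(np.clip(-dg / (R_GAS * t), -500, 500)))
            out.append(ff * (qf0 + qf1 * t) + (1 - ff) * (qu0 + qu1 * t))
        return np.concatenate(out)

    sem_all = np.concatenate([sa, sb])

    def resid(theta):
        return (model(theta) - q_all) / sem_all

    t_all = np.concatenate([ta, tb])
    base_lo, base_hi = [-1.0, -0.01, -1.0, -0.01], [2.0, 0.01, 2.0, 0.01]
    if share_dh:
        lo = [t_all.min() * 0.5] * 2 + [1.0] + base_lo
        hi = [t_all.max() * 2.0] * 2 + [np.inf] + base_hi
    else:
        lo = [t_all.min() * 0.5, 1.0] * 2 + base_lo
        hi = [t_all.max() * 2.0, np.inf] * 2 + base_hi
    sol = least_squares(resid, theta0, bounds=(lo, hi), method="trf", xtol=1e-12, ftol=1e-12)
    if not sol.success:
        raise RuntimeError(f"paired two-state fit did not converge: {sol.message}")
    n_par = len(sol.x)
    dof = max(len(q_all) - n_par, 1)
    try:
        cov = np.linalg.inv(sol.jac.T @ sol.jac) * 2.0 * sol.cost / dof
    except np.linalg.LinAlgError:
        cov = np.full((n_par, n_par), np.nan)
    names = ("tm", "dh_vh", "qf0", "qf1", "qu0", "qu1")
    if share_dh:
        picks = ([0, 2, 3, 4, 5, 6], [1, 2, 3, 4, 5, 6])
        vals = [(sol.x[0], sol.x[2]), (sol.x[1], sol.x[2])]
        base = tuple(sol.x[3:7])
    else:
        picks = ([0, 1, 4, 5, 6, 7], [2, 3, 4, 5, 6, 7])
        vals = [(sol.x[0], sol.x[1]), (sol.x[2], sol.x[3])]
        base = tuple(sol.x[4:8])
    fits = []
    for (tm, dh), idx in zip(vals, picks):
        fits.append(TwoStateFit(
            tm=float(tm), dh_vh=float(dh), dcp=0.0,
            baseline_folded=(float(base[0]), float(base[1])),
            baseline_unfolded=(float(base[2]), float(base[3])),
            covariance=cov[np.ix_(idx, idx)],
            param_names=names,
        ))
    return fits[0], fits[1]


@dataclass(frozen=True)
class StabilityComparison:
    """Mutant-minus-wildtype stability difference at one temperature."""

    delta_tm: float       # K
    ddg: float            # kJ/mol, ΔG_u^mut − ΔG_u^wt at `temperature`
    temperature: float    # K
    ddg_uncertainty: float

    def to_dict(self) -> dict:
        return {
            "delta_tm_K": self.delta_tm,
            "ddg_kJ_mol": self.ddg,
            "temperature_K": self.temperature,
            "ddg_uncertainty_kJ_mol": self.ddg_uncertainty,
        }


def delta_delta_g(fit_wt: TwoStateFit, fit_mut: TwoStateFit, temperature: float) -> StabilityComparison:
    """ΔΔG_u(T) = ΔG_u^mut(T) − ΔG_u^wt(T), with first-order propagated
    uncertainty; negative = destabilising mutation."""
    ddg = float(fit_mut.dg_u(temperature) - fit_wt.dg_u(temperature))
    var = fit_mut.dg_u_variance(temperature) + fit_wt.dg_u_variance(temperature)
    return StabilityComparison(
        delta_tm=fit_mut.tm - fit_wt.tm,
        ddg=ddg,
        temperature=float(temperature),
        ddg_uncertainty=float(np.sqrt(max(var, 0.0))),
    )


def celsius_to_kelvin(t_celsius: float) -> float:
    return t_celsius + 273.15


def load_melting_curve_tsv(path: str, n_blocks: int = 12, burn_in_fraction: float = 0.4) -> MeltingCurve:
    """Read a Teff/⟨Q_N⟩/sem table (TSV with header teff_K, qn_mean,
    qn_sem), e.g. a curve derived from deposited trajectories."""
    data = np.loadtxt(path, skiprows=1)
    data = data[np.argsort(data[:, 0])]
    return MeltingCurve(
        teff=data[:, 0], qn_mean=data[:, 1], qn_sem=data[:, 2],
        n_blocks=n_blocks, burn_in_fraction=burn_in_fraction,
    )


def write_fit_json(fit: TwoStateFit, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(fit.to_dict(), fh, indent=2)
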