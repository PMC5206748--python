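"""One-site ITC isotherm and 1:1 SPR kinetics: simulation and fitting.

ITC
---
The calorimeter titrates ligand (syringe, total concentration ``Xt`` in
the cell after dilution) into macromolecule (cell, ``Mt``).  For a single
class of sites with stoichiometry ``n``, association constant ``K`` (M⁻¹)
and molar enthalpy ``ΔH`` (cal/mol), the cumulative heat after reaching
(Mt, Xt) is the closed form

    Q = n·Mt·ΔH·V0/2 · [1 + Xt/(n·Mt) + 1/(n·K·Mt)
                        − sqrt((1 + Xt/(n·Mt) + 1/(n·K·Mt))² − 4·Xt/(n·Mt))]

Per-injection heats are differences of Q with the standard perfusion-cell
displaced-volume correction; active concentrations are diluted by
(1 − dV/V0) at every injection.  The stoichiometry ``n`` is the business
end here: an antibody that can decorate every protomer of a dimer fits
n ≈ 0.7–0.8 per antibody (equimolar), while an antibody that can occupy
only one protomer of a locked dimer doubles it to n ≈ 1.5.

SPR
---
Pseudo-first-order 1:1 Langmuir kinetics at constant analyte
concentration C:

    association:  R(t) = Req·(1 − e^−(C·kon+koff)·t),  Req = C·kon·Rmax/(C·kon+koff)
    dissociation: R(t) = R_end·e^−koff·(t−t_a)

fitted globally — one shared (kon, koff, Rmax) across all concentrations —
with KD = koff/kon.  No mass-transport term is modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import FitConvergenceError

CAL_TO_UCAL = 1e6


# ---------------------------------------------------------------------------
# ITC


@dataclass
class ItcExperiment:
    """Layout and measured (or simulated) per-injection heats."""

    cell_concentration: float  # M, macromolecule (antibody) in the cell
    syringe_concentration: float  # M, titrant (cadherin construct)
    cell_volume: float  # L
    injection_volumes: np.ndarray  # L, per injection
    heats: np.ndarray  # μcal, per injection
    temperature: float = 288.15  # K

    def __post_init__(self) -> None:
        self.injection_volumes = np.asarray(self.injection_volumes, float)
        self.heats = np.asarray(self.heats, float)
        if self.cell_concentration <= 0 or self.syringe_concentration <= 0:
            raise ValueError("concentrations must be positive")
        if len(self.heats) != len(self.injection_volumes):
            raise ValueError("heats and injection_volumes length mismatch")

    def concentration_schedule(self) -> tuple[np.ndarray, np.ndarray]:
        """Active (Mt, Xt) in the cell after each injection, with dilution."""
        Mt = np.empty(len(self.injection_volumes))
        Xt = np.empty(len(self.injection_volumes))
        m, x = self.cell_concentration, 0.0
        for i, dv in enumerate(self.injection_volumes):
            f = dv / self.cell_volume
            m *= 1.0 - f
            x = x * (1.0 - f) + self.syringe_concentration * f
            Mt[i], Xt[i] = m, x
        return Mt, Xt

    def molar_ratio(self) -> np.ndarray:
        Mt, Xt = self.concentration_schedule()
        return Xt / Mt


@dataclass
class ItcFit:
    n: float  # stoichiometry, sites per cell molecule
    K: float  # association constant, M^-1
    dH: float  # cal/mol
    offset: float  # μcal per injection, baseline nuisance
    stderr: dict[str, float] = field(default_factory=dict)
    residuals: np.ndarray | None = None
    molar_ratio: np.ndarray | None = None

    @property
    def Kd(self) -> float:
        return 1.0 / self.K


def _cumulative_heat(n, K, dH, Mt, Xt, V0):
    """Closed-form one-site cumulative heat (cal) at each (Mt, Xt)."""
    a = 1.0 + Xt / (n * Mt) + 1.0 / (n * K * Mt)
    disc = np.maximum(a * a - 4.0 * Xt / (n * Mt), 0.0)
    return n * Mt * dH * V0 / 2.0 * (a - np.sqrt(disc))


def itc_injection_heats(
    n: float, K: float, dH: float, experiment: ItcExperiment, offset: float = 0.0
) -> np.ndarray:
    """Model per-injection heats (μcal) incl. displaced-volume correction."""
    V0 = experiment.cell_volume
    Mt, Xt = experiment.concentration_schedule()
    Q = _cumulative_heat(n, K, dH, Mt, Xt, V0)
    dQ = np.empty_like(Q)
    q_prev = 0.0
    for i, dv in enumerate(experiment.injection_volumes):
        dQ[i] = Q[i] - q_prev + (dv / V0) * (Q[i] + q_prev) / 2.0
        q_prev = Q[i]
    return dQ * CAL_TO_UCAL + offset


def simulate_itc(
    n: float,
    K: float,
    dH: float,
    *,
    cell_concentration: float,
    syringe_concentration: float,
    cell_volume: float = 200e-6 * 1e-3,  # 200 μL working cell, in L
    n_injections: int = 20,
    injection_volume: float = 2e-6 * 1e-3,  # 2 μL, in L
    noise_sd: float = 0.0,
    seed: int | None = None,
    temperature: float = 288.15,
) -> ItcExperiment:
    """Simulate a one-site titration; ``noise_sd`` is Gaussian, in μcal."""
    if n <= 0 or K <= 0:
        raise ValueError("n and K must be positive")
    vols = np.full(n_injections, injection_volume)
    exp = ItcExperiment(
        cell_concentration=cell_concentration,
        syringe_concentration=syringe_concentration,
        cell_volume=cell_volume,
        injection_volumes=vols,
        heats=np.zeros(n_injections),
        temperature=temperature,
    )
    heats = itc_injection_heats(n, K, dH, exp)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        heats = heats + rng.normal(0.0, noise_sd, size=heats.shape)
    exp.heats = heats
    return exp


def _itc_k_heuristic(experiment: ItcExperiment) -> float:
    """Association-constant starting guess from the isotherm's transition width.

    For a one-site isotherm the molar-ratio width of the 25%→75% saturation
    transition shrinks roughly like 1/c with c = n·K·Mt; inverting that
    gives an order-of-magnitude K.
    """
    ratio = experiment.molar_ratio()
    h = experiment.heats - experiment.heats[-1]
    total = np.cumsum(np.abs(h))
    if total[-1] <= 0:
        return 1e7
    frac = total / total[-1]
    try:
        r25 = ratio[np.searchsorted(frac, 0.25)]
        r75 = ratio[np.searchsorted(frac, 0.75)]
    except IndexError:
        return 1e7
    width = max(float(r75 - r25), 1e-3)
    c = max(4.0 / width, 1.0)
    Mt = experiment.cell_concentration
    return float(np.clip(c / Mt, 1e3, 1e12))


def fit_itc(
    experiment: ItcExperiment,
    *,
    skip_first: bool = True,
    fit_offset: bool = True,
) -> ItcFit:
    """Nonlinear least-squares one-site fit of per-injection heats.

    The first injection is excluded by default (standard practice: its
    heat is corrupted by diffusion across the syringe tip during
    equilibration).  Multi-start over n ∈ {0.5, 1, 1.5, 2}; ties broken by
    residual norm, then by lower n.  Standard errors come from the
    Jacobian at the optimum.
    """
    if len(experiment.heats) < 8:
        raise ValueError("need at least 8 injections to fit")
    mask = np.ones(len(experiment.heats), dtype=bool)
    if skip_first:
        mask[0] = False
    y = experiment.heats[mask]
    K0 = _itc_k_heuristic(experiment)
    # crude ΔH scale: heat of an early injection per mole injected
    inj_moles = experiment.syringe_concentration * experiment.injection_volumes[1]
    dH0 = float(np.clip(experiment.heats[1] * 1e-6 / inj_moles, -1e6, 1e6))
    if dH0 == 0.0:
        dH0 = -1e3

    def residual(x):
        n, logK, dH, off = x
        model = itc_injection_heats(n, 10.0**logK, dH, experiment, off)[mask]
        return model - y

    best = None
    for n0 in (0.5, 1.0, 1.5, 2.0):
        x0 = np.array([n0, np.log10(K0), dH0, 0.0])
        bounds = (
            [1e-3, 2.0, -1e8, -np.inf if fit_offset else -1e-12],
            [10.0, 14.0, 1e8, np.inf if fit_offset else 1e-12],
        )
        try:
            res = least_squares(residual, x0, bounds=bounds, method="trf", xtol=1e-14,
                                ftol=1e-14, gtol=1e-14)
        except Exception:
            continue
        if best is None or res.cost < best.cost - 1e-12 or (
            abs(res.cost - best.cost) <= 1e-12 and res.x[0] < best.x[0]
        ):
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise FitConvergenceError("ITC fit failed from all starts")
    n_hat, logK_hat, dH_hat, off_hat = best.x
    stderr = _stderr_from_jacobian(best, ["n", "logK", "dH", "offset"])
    if "logK" in stderr:
        stderr["K"] = np.log(10.0) * 10.0**logK_hat * stderr.pop("logK")
    return ItcFit(
        n=float(n_hat),
        K=float(10.0**logK_hat),
        dH=float(dH_hat),
        offset=float(off_hat),
        stderr=stderr,
        residuals=best.fun,
        molar_ratio=experiment.molar_ratio()[mask],
    )


# ---------------------------------------------------------------------------
# SPR


@dataclass
class SprExperiment:
    """Sensorgrams at several analyte concentrations, long format.

    ``data`` columns: concentration_M, time_s, RU, phase ('association' or
    'dissociation'); dissociation times continue the association clock.
    """

    data: pd.DataFrame
    association_time: float  # s
    dissociation_time: float  # s

    def __post_init__(self) -> None:
        required = {"concentration_M", "time_s", "RU", "phase"}
        if not required <= set(self.data.columns):
            raise ValueError(f"sensorgram table needs columns {sorted(required)}")
        for _, g in self.data.groupby("concentration_M"):
            t = g["time_s"].to_numpy()
            if np.any(np.diff(t) <= 0):
                raise ValueError("time must be strictly increasing per concentration")

    @property
    def concentrations(self) -> np.ndarray:
        return np.sort(self.data["concentration_M"].unique())


@dataclass
class KineticFit:
    kon: float  # M^-1 s^-1
    koff: float  # s^-1
    Rmax: float  # RU
    stderr: dict[str, float] = field(default_factory=dict)
    residual_norm: float = 0.0

    @property
    def KD(self) -> float:
        return self.koff / self.kon


def sensorgram_model(
    kon: float,
    koff: float,
    Rmax: float,
    concentration: float,
    times: np.ndarray,
    association_time: float,
) -> np.ndarray:
    """1:1 Langmuir response at one concentration over the full time course."""
    t = np.asarray(times, float)
    C = concentration
    kobs = C * kon + koff
    Req = C * kon * Rmax / kobs if kobs > 0 else 0.0
    R = np.where(
        t <= association_time,
        Req * (1.0 - np.exp(-kobs * np.minimum(t, association_time))),
        0.0,
    )
    r_end = Req * (1.0 - np.exp(-kobs * association_time))
    diss = t > association_time
    R[diss] = r_end * np.exp(-koff * (t[diss] - association_time))
    return R


def simulate_sensorgram(
    kon: float,
    koff: float,
    Rmax: float,
    concentrations: list[float],
    *,
    association_time: float = 120.0,
    dissociation_time: float = 300.0,
    dt: float = 1.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> SprExperiment:
    """Simulate a concentration series of 1:1 sensorgrams (noise in RU)."""
    if kon <= 0 or koff <= 0 or Rmax <= 0:
        raise ValueError("kon, koff, Rmax must be positive")
    rng = np.random.default_rng(seed)
    times = np.arange(dt, association_time + dissociation_time + dt / 2, dt)
    rows = []
    for C in concentrations:
        R = sensorgram_model(kon, koff, Rmax, C, times, association_time)
        if noise_sd > 0:
            R = R + rng.normal(0.0, noise_sd, size=R.shape)
        rows.append(
            pd.DataFrame(
                {
                    "concentration_M": C,
                    "time_s": times,
                    "RU": R,
                    "phase": np.where(
                        times <= association_time, "association", "dissociation"
                    ),
                }
            )
        )
    return SprExperiment(
        pd.concat(rows, ignore_index=True),
        association_time=association_time,
        dissociation_time=dissociation_time,
    )


def fit_spr_global(experiment: SprExperiment) -> KineticFit:
    """Global 1:1 fit: one shared (kon, koff, Rmax) across all concentrations."""
    concs = experiment.concentrations
    if len(concs) < 2:
        raise ValueError("global fit needs >= 2 analyte concentrations")
    groups = [
        (float(C), g["time_s"].to_numpy(), g["RU"].to_numpy())
        for C, g in experiment.data.groupby("concentration_M")
    ]
    t_a = experiment.association_time
    y = np.concatenate([ru for _, _, ru in groups])
    r_scale = max(float(np.abs(y).max()), 1.0)

    def residual(x):
        kon, koff, Rmax = 10.0 ** x[0], 10.0 ** x[1], x[2]
        model = np.concatenate(
            [sensorgram_model(kon, koff, Rmax, C, t, t_a) for C, t, _ in groups]
        )
        return model - y

    # start from kobs ≈ 0.01 s⁻¹ at the median concentration, a mid-range
    # guess for antibody-scale kinetics; multi-start shifts it either way
    c_mid = float(np.median(concs))
    kon0 = np.clip(np.log10(0.01 / c_mid) if c_mid > 0 else 6.0, 1.0, 11.0)
    x0 = np.array([kon0, -2.0, r_scale])
    best = None
    for dk in (0.0, 1.5, -1.5):
        try:
            res = least_squares(
                residual,
                np.clip(x0 + np.array([dk, dk, 0.0]), [0.0, -8.0, 1e-6], [12.0, 2.0, 1e6]),
                bounds=([0.0, -8.0, 1e-6], [12.0, 2.0, 1e6]),
                method="trf",
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise FitConvergenceError("SPR global fit failed")
    kon, koff, Rmax = 10.0 ** best.x[0], 10.0 ** best.x[1], best.x[2]
    stderr = _stderr_from_jacobian(best, ["logkon", "logkoff", "Rmax"])
    out = {}
    if "logkon" in stderr:
        out["kon"] = np.log(10.0) * kon * stderr["logkon"]
        out["koff"] = np.log(10.0) * koff * stderr["logkoff"]
        out["Rmax"] = stderr["Rmax"]
    return KineticFit(
        kon=float(kon),
        koff=float(koff),
        Rmax=float(Rmax),
        stderr=out,
        residual_norm=float(np.sqrt(2 * best.cost)),
    )


# ---------------------------------------------------------------------------
# File dialects


def load_itc(header_yaml: str | Path, heats_csv: str | Path) -> ItcExperiment:
    """Read an experiment from a YAML header + (injection_volume_uL, heat_ucal) CSV."""
    import yaml as _yaml

    header = _yaml.safe_load(Path(header_yaml).read_text())
    df = pd.read_csv(heats_csv)
    return ItcExperiment(
        cell_concentration=float(header["cell_concentration_M"]),
        syringe_concentration=float(header["syringe_concentration_M"]),
        cell_volume=float(header["cell_volume_L"]),
        injection_volumes=df["injection_volume_uL"].to_numpy() * 1e-6 * 1e-3,
        heats=df["heat_ucal"].to_numpy(),
        temperature=float(header.get("temperature_K", 288.15)),
    )


def save_itc(experiment: ItcExperiment, header_yaml: str | Path, heats_csv: str | Path) -> None:
    import yaml as _yaml

    Path(header_yaml).write_text(
        _yaml.safe_dump(
            {
                "cell_concentration_M": float(experiment.cell_concentration),
                "syringe_concentration_M": float(experiment.syringe_concentration),
                "cell_volume_L": float(experiment.cell_volume),
                "temperature_K": float(experiment.temperature),
            }
        )
    )
    pd.DataFrame(
        {
            "injection_volume_uL": experiment.injection_volumes * 1e9,
            "heat_ucal": experiment.heats,
        }
    ).to_csv(heats_csv, index=False)


def load_spr(csv_path: str | Path) -> SprExperiment:
    """Read a long-format (concentration_M, time_s, RU, phase) sensorgram CSV."""
    df = pd.read_csv(csv_path)
    assoc = df[df["phase"] == "association"]["time_s"]
    t_a = float(assoc.max()) if len(assoc) else 0.0
    t_max = float(df["time_s"].max())
    return SprExperiment(df, association_time=t_a, dissociation_time=t_max - t_a)


def save_spr(experiment: SprExperiment, csv_path: str | Path) -> None:
    experiment.data.to_csv(csv_path, index=False)


def _stderr_from_jacobian(res, names: list[str]) -> dict[str, float]:
    m, p = res.jac.shape
    if m <= p:
        return {}
    s2 = 2.0 * res.cost / (m - p)
    try:
        cov = s2 * np.linalg.inv(res.jac.T @ res.jac)
    except np.linalg.LinAlgError:
        return {}
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    return dict(zip(names, (float(v) for v in se)))
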