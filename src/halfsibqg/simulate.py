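"""Synthetic split-brood half-sib data with known genetic architecture.

The generator emulates a paternal half-sib / full-sib breeding design in
which each sire is mated to several dams and every dam's brood is split
between an ethanol-free (0%) and an ethanol-supplemented (7%) rearing
environment.  Trait expression in the two environments is modelled as a
character state: each founder carries a 10-dimensional breeding value
(5 traits × 2 environments) drawn from the block covariance

    [[G0, B], [B', G7]],   B[i,i] = rho_ge * sqrt(G0[i,i] * G7[i,i])

with zero cross-trait cross-environment covariance; offspring receive the
parental mid-value plus a Mendelian deviate with half that covariance.
Phenotypes on the log10 scale add dam (common-environment), replicate-line
and residual effects plus fixed effects of population, environment and
sex; routine metabolic rate additionally gets a body-mass slope and
chamber/hour effects.  Total development time is the raw-scale sum of the
larval and pupal times by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pedigree import Pedigree
from .phenotypes import TRAITS, COLUMNS, PhenotypeTable
from .respirometry import RespirometryRecord, PPM_TO_RATE

N_TRAITS = 5
ENVS = ("0", "7")          # percent ethanol
SEXES = ("F", "M")

# raw-scale trait means (days, days, days, mg, µL CO₂ h⁻¹); arbitrary
# figure-scale defaults, not estimates from any dataset
DEFAULT_RAW_MEANS = (22.0, 11.0, 33.0, 1.0, 60.0)
# total phenotypic variance per trait on the log10 scale
DEFAULT_T = (0.004, 0.004, 0.004, 0.006, 0.010)
DEFAULT_H2 = (0.3, 0.2, 0.3, 0.15, 0.10)
DEFAULT_C_FRAC = 0.15
DEFAULT_R_FRAC = 0.05


class SimulationError(ValueError):
    pass


def _diag_from(fracs, totals) -> np.ndarray:
    return np.diag(np.asarray(fracs) * np.asarray(totals))


@dataclass
class SimulationConfig:
    """Study-design and genetic-architecture parameters for the generator."""

    populations: tuple[str, ...] = ("SF", "VD")
    n_sires: tuple[int, ...] = (29, 16)
    dams_per_sire: int = 4
    offspring_per_dam_per_env: int = 6
    n_lines: tuple[int, ...] = (3, 3)
    envs: tuple[str, ...] = ENVS

    G0: np.ndarray = None
    G7: np.ndarray = None
    C: np.ndarray = None
    R: np.ndarray = None
    E: np.ndarray = None
    rho_ge: float = 0.5

    trait_means_log10: np.ndarray = None
    #: per-population log10 shift in environment "7" relative to "0"
    env_shift: dict = None
    #: log10 shift added to females
    sex_effect: np.ndarray = None
    #: per-population log10 shift relative to the first population
    pop_shift: dict = None

    beta_mass: float = 0.65
    chamber_effects: np.ndarray = None   # length 7, log10 RMR
    hour_effects: np.ndarray = None      # length 9, log10 RMR
    flies_per_record: int = 7
    records_per_day: int = 9

    seed: int = 0

    def __post_init__(self):
        T = np.asarray(DEFAULT_T)
        if self.G0 is None:
            self.G0 = _diag_from(DEFAULT_H2, T)
        if self.G7 is None:
            self.G7 = _diag_from(DEFAULT_H2, T)
        if self.C is None:
            self.C = np.diag(DEFAULT_C_FRAC * T)
        if self.R is None:
            self.R = np.diag(DEFAULT_R_FRAC * T)
        if self.E is None:
            e_frac = 1.0 - np.asarray(DEFAULT_H2) - DEFAULT_C_FRAC - DEFAULT_R_FRAC
            self.E = _diag_from(e_frac, T)
        for name in ("G0", "G7", "C", "R", "E"):
            m = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, m)
            if m.shape != (N_TRAITS, N_TRAITS):
                raise SimulationError(f"{name} must be {N_TRAITS}x{N_TRAITS}")
            if not np.allclose(m, m.T):
                raise SimulationError(f"{name} must be symmetric")
            if np.linalg.eigvalsh(m).min() < -1e-10:
                raise SimulationError(f"{name} is not positive semidefinite")
        if abs(self.rho_ge) > 1:
            raise SimulationError("|rho_ge| must be <= 1")
        if self.trait_means_log10 is None:
            self.trait_means_log10 = np.log10(DEFAULT_RAW_MEANS)
        self.trait_means_log10 = np.asarray(self.trait_means_log10, dtype=float)
        if self.env_shift is None:
            # second population plastic for development time; both lose mass
            # and depress RMR under ethanol (qualitative defaults)
            self.env_shift = {}
            for k, p in enumerate(self.populations):
                dev = 0.0 if k == 0 else 0.02
                self.env_shift[p] = np.array([dev, 0.0, dev, -0.01, -0.02])
        if self.pop_shift is None:
            self.pop_shift = {
                p: np.array([0.0, 0.005 * k, 0.0, -0.01 * k, -0.015 * k])
                for k, p in enumerate(self.populations)
            }
        if self.sex_effect is None:
            self.sex_effect = np.array([0.0, 0.0, 0.0, 0.04, 0.02])
        self.sex_effect = np.asarray(self.sex_effect, dtype=float)
        if self.chamber_effects is None:
            self.chamber_effects = np.linspace(-0.006, 0.006, self.flies_per_record)
        if self.hour_effects is None:
            self.hour_effects = np.linspace(-0.008, 0.008, self.records_per_day)
        self.chamber_effects = np.asarray(self.chamber_effects, dtype=float)
        self.hour_effects = np.asarray(self.hour_effects, dtype=float)
        if len(self.n_sires) != len(self.populations):
            raise SimulationError("n_sires must match populations")
        if len(self.n_lines) != len(self.populations):
            raise SimulationError("n_lines must match populations")
        # block cross-environment covariance must be PSD before sampling
        self.block_cov()

    def block_cov(self) -> np.ndarray:
        """10×10 character-state covariance [[G0,B],[B',G7]]; validated PSD."""
        B = np.diag(
            self.rho_ge * np.sqrt(np.diag(self.G0) * np.diag(self.G7))
        )
        M = np.block([[self.G0, B], [B.T, self.G7]])
        if np.linalg.eigvalsh(M).min() < -1e-10:
            raise SimulationError(
                "cross-environment block covariance is not positive semidefinite "
                "(|rho_ge| too large for these G0/G7 diagonals)"
            )
        return M


@dataclass
class TruthRecord:
    """Ground truth behind one simulated dataset (for recovery tests)."""

    config: SimulationConfig
    breeding_values: pd.DataFrame      # individual × (trait, env) columns
    dam_effects: pd.DataFrame          # (dam, env) × trait
    line_effects: pd.DataFrame         # (population, line, env) × trait


def _mvn(rng, cov, size):
    """Deterministic MVN draws via Cholesky of a PSD matrix (jittered)."""
    d = cov.shape[0]
    w, V = np.linalg.eigh(cov)
    w = np.clip(w, 0.0, None)
    Lfac = V * np.sqrt(w)
    z = rng.standard_normal((size, d))
    return z @ Lfac.T


def simulate_design(cfg: SimulationConfig):
    """Simulate (Pedigree, raw PhenotypeTable, TruthRecord) for the design.

    Offspring rows = sum(n_sires) × dams_per_sire × offspring_per_dam_per_env
    × n_envs; the pedigree additionally lists every sire and dam as a
    founder row.  Bit-reproducible from (cfg, cfg.seed).
    """
    rng = np.random.default_rng(cfg.seed)
    block = cfg.block_cov()
    n_env = len(cfg.envs)

    entries = []
    rows = []
    bv_rows = {}
    dam_eff_rows = []
    line_eff_rows = []

    for p_idx, pop in enumerate(cfg.populations):
        n_s = cfg.n_sires[p_idx]
        n_l = cfg.n_lines[p_idx]
        # round-robin assignment of sires to replicate lines
        line_of_sire = [f"{pop}_L{(k % n_l) + 1}" for k in range(n_s)]
        line_labels = [f"{pop}_L{j + 1}" for j in range(n_l)]
        line_eff = {
            (ln, env): _mvn(rng, cfg.R, 1)[0]
            for ln in line_labels
            for env in cfg.envs
        }
        for (ln, env), v in line_eff.items():
            line_eff_rows.append((pop, ln, env, *v))

        for s in range(n_s):
            sire = f"{pop}_s{s + 1:02d}"
            a_sire = _mvn(rng, block, 1)[0]
            bv_rows[sire] = a_sire
            entries.append((sire, None, None))
            line = line_of_sire[s]
            for d in range(cfg.dams_per_sire):
                dam = f"{sire}_d{d + 1}"
                a_dam = _mvn(rng, block, 1)[0]
                bv_rows[dam] = a_dam
                entries.append((dam, None, None))
                dam_eff = {env: _mvn(rng, cfg.C, 1)[0] for env in cfg.envs}
                for env in cfg.envs:
                    dam_eff_rows.append((dam, env, *dam_eff[env]))
                mid = 0.5 * (a_sire + a_dam)
                for env_idx, env in enumerate(cfg.envs):
                    sl = slice(env_idx * N_TRAITS, (env_idx + 1) * N_TRAITS)
                    for o in range(cfg.offspring_per_dam_per_env):
                        ind = f"{dam}_e{env}_{o + 1}"
                        a_ind = mid + _mvn(rng, 0.5 * block, 1)[0]
                        bv_rows[ind] = a_ind
                        entries.append((ind, sire, dam))
                        sex = SEXES[rng.integers(0, 2)]
                        e = _mvn(rng, cfg.E, 1)[0]
                        y = (
                            cfg.trait_means_log10
                            + cfg.pop_shift[pop]
                            + (cfg.env_shift[pop] if env_idx > 0 else 0.0)
                            + (cfg.sex_effect if sex == "F" else 0.0)
                            + a_ind[sl]
                            + dam_eff[env]
                            + line_eff[(line, env)]
                            + e
                        )
                        rows.append([ind, pop, line, env, sex, y])

    # respirometry schedule: records of `flies_per_record` flies in a
    # permuted order; chamber = slot within record, hour cycles per day
    order = rng.permutation(len(rows))
    chambers = np.empty(len(rows), dtype=object)
    hours = np.empty(len(rows), dtype=object)
    for pos, row_i in enumerate(order):
        rec = pos // cfg.flies_per_record
        chambers[row_i] = f"ch{(pos % cfg.flies_per_record) + 1}"
        hours[row_i] = f"h{rec % cfg.records_per_day}"

    mean_log_mb = cfg.trait_means_log10[3]
    out = []
    for k, (ind, pop, line, env, sex, y) in enumerate(rows):
        y = y.copy()
        # RMR fixed effects: mass slope, chamber, hour (log10 scale)
        ch_i = int(chambers[k][2:]) - 1
        h_i = int(hours[k][1:])
        y[4] += (
            cfg.beta_mass * (y[3] - mean_log_mb)
            + cfg.chamber_effects[ch_i]
            + cfg.hour_effects[h_i]
        )
        raw = 10.0 ** y
        ldt, pdt = raw[0], raw[1]
        tdt = ldt + pdt          # total development is the raw-scale sum
        out.append(
            [ind, pop, line, env, sex, chambers[k], hours[k],
             ldt, pdt, tdt, raw[3], raw[4]]
        )

    ped = Pedigree.from_entries(entries)
    tab = PhenotypeTable(
        df=pd.DataFrame(out, columns=list(COLUMNS)), scale="raw"
    )
    # breeding values are 10-dimensional character states regardless of
    # how many environments are actually reared
    bv_cols = [f"{t}_{env}" for env in ENVS for t in TRAITS]
    truth = TruthRecord(
        config=cfg,
        breeding_values=pd.DataFrame.from_dict(
            bv_rows, orient="index", columns=bv_cols
        ),
        dam_effects=pd.DataFrame(
            dam_eff_rows, columns=["dam", "env", *TRAITS]
        ),
        line_effects=pd.DataFrame(
            line_eff_rows, columns=["population", "line", "env", *TRAITS]
        ),
    )
    return ped, tab, truth


# ----------------------------------------------------------------------
# Raw respirometry traces
# ----------------------------------------------------------------------
def simulate_respirometry_day(
    n_records: int = 9,
    flies_per_record: int = 7,
    drift: tuple[float, float] = (2.0, 0.05),
    noise_sd: float = 0.0,
    true_rmr=30.0,
    flow_rate: float = 50.0,
    seed: int = 0,
    duration_per_fly: float = 10.0,
    samples_per_minute: float = 2.0,
) -> list[RespirometryRecord]:
    """Simulate one day of multiplexed CO₂ traces.

    Each record reads the empty baseline chamber at the beginning, middle
    and end, with a linear analyzer drift b(t) = b0 + b1·t, and each fly
    chamber for ``duration_per_fly`` minutes at ppm = drift + rmr/(flow ×
    conversion) + noise.  ``true_rmr`` may be a scalar or one value per fly
    (n_records × flies_per_record total).
    """
    if flow_rate <= 0:
        raise SimulationError("flow_rate must be positive")
    rng = np.random.default_rng(seed)
    n_flies = n_records * flies_per_record
    rmr = np.broadcast_to(np.asarray(true_rmr, dtype=float), (n_flies,))
    b0, b1 = drift
    records = []
    for r in range(n_records):
        times, chambers, ppm = [], [], []
        total = flies_per_record * duration_per_fly
        assignment = {}
        # baseline at begin / middle / end
        base_times = [0.0, total / 2, total]
        for f in range(flies_per_record):
            fly = f"day_r{r + 1}_f{f + 1}"
            chamber = f"ch{f + 1}"
            assignment[fly] = chamber
            t0 = f * duration_per_fly
            n_samp = max(2, int(duration_per_fly * samples_per_minute))
            ts = t0 + np.linspace(0.1, duration_per_fly - 0.1, n_samp)
            excess = rmr[r * flies_per_record + f] / (flow_rate * PPM_TO_RATE)
            vals = b0 + b1 * ts + excess + noise_sd * rng.standard_normal(n_samp)
            times.extend(ts)
            chambers.extend([chamber] * n_samp)
            ppm.extend(vals)
        for bt in base_times:
            times.append(bt)
            chambers.append("B")
            ppm.append(b0 + b1 * bt + noise_sd * rng.standard_normal())
        order = np.argsort(times, kind="stable")
        records.append(
            RespirometryRecord(
                times=np.asarray(times)[order],
                chambers=np.asarray(chambers, dtype=object)[order],
                ppm=np.asarray(ppm)[order],
                baseline_chamber="B",
                flow_rate=flow_rate,
                fly_assignment=assignment,
                duration_per_fly=duration_per_fly,
                record_hour=f"h{r}",
            )
        )
    return records
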