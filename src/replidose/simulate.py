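"""Synthetic data with known ground truth for every estimator.

The generator emulates the inputs of the analysis battery:

* replication-dependent read dosage along two co-terminating circular
  chromosomes (the Cooper–Helmstetter style gene-dosage gradient, an
  inverted "V" of copy number peaking at each origin),
* paired exponential/stationary sequencing window counts with optional
  negative-binomial overdispersion, collapsed-repeat artifacts and a
  deletion,
* logistic plate-reader kinetic curves,
* flow-cytometry competition counts,
* biphasic antibiotic kill curves.

Every simulator is a pure function of its arguments including the seed,
so parameter-recovery tests are exact and reproducible.

The dosage model: during steady-state exponential growth a locus at
relative replication distance ``d`` from the origin (``d = 0`` at ori,
``1`` at ter) has expected copy number ``2**(c_over_tau * (1 - d))``
per terminus equivalent, where ``c_over_tau`` is the replication period
divided by the doubling time.  With co-termination the secondary
chromosome fires late so its forks finish with the primary's: its
effective exponent is scaled by the ratio of arm lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .genome import Replicon, tile_windows
from .kinetics import KineticSeries, logistic
from .mfa import WindowCounts

__all__ = [
    "GrowthParams",
    "SimConfig",
    "ExpectedDosage",
    "CompetitionCount",
    "CompetitionAssay",
    "KillCurve",
    "sim_copy_number",
    "sim_read_windows",
    "inject_artifacts",
    "sim_kinetic_curve",
    "sim_competition",
    "sim_kill_curve",
    "kill_curve_expected",
    "simulate_mfa_dataset",
    "ground_truth",
    "load_sim_config",
    "default_study_config",
]


@dataclass(frozen=True)
class GrowthParams:
    """Replication regime of the simulated culture.

    ``c_over_tau`` is the time to replicate the longest arm divided by
    the doubling time (dimensionless; 0 means stationary phase, flat
    dosage).  With ``co_terminate`` the shorter replicon initiates late
    enough that all forks finish together — the known behaviour of
    secondary chromosomes in *Vibrio*.  ``fork_speed_equal`` places the
    terminus antipodal to the origin.
    """

    c_over_tau: float = 1.0
    co_terminate: bool = True
    fork_speed_equal: bool = True

    def __post_init__(self) -> None:
        if self.c_over_tau < 0:
            raise ValueError("c_over_tau must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    """Full configuration of a synthetic MFA dataset (maps 1:1 to YAML)."""

    replicons: tuple[Replicon, ...]
    growth: GrowthParams = GrowthParams()
    total_reads: int = 2_000_000
    dispersion: float = 0.02
    window_bp: int = 1_000
    repeat_artifacts: tuple[tuple[str, int, int, float], ...] = ()
    deletion: tuple[str, int, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total_reads <= 0:
            raise ValueError("total_reads must be > 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        by_name = {r.name: r for r in self.replicons}
        for name, start, end, _mult in self.repeat_artifacts:
            _check_interval(by_name, name, start, end, "repeat artifact")
        if self.deletion is not None:
            _check_interval(by_name, *self.deletion, what="deletion")


def _check_interval(by_name, name, start, end, what):
    rep = by_name.get(name)
    if rep is None:
        raise ValueError(f"{what} on unknown replicon {name!r}")
    if not 0 <= start < end <= rep.length_bp:
        raise ValueError(f"{what} interval [{start}, {end}) outside {name!r}")


@dataclass(frozen=True)
class ExpectedDosage:
    """Per-window expected relative copy number (mean 1 over non-deleted
    windows of all replicons; exactly 0 inside a simulated deletion)."""

    df: pd.DataFrame  # replicon, start, end, dosage
    window_bp: int
    replicons: tuple[Replicon, ...]
    deletion: tuple[str, int, int] | None = None

    def values(self) -> np.ndarray:
        return self.df["dosage"].to_numpy(dtype=float)


def _arm_geometry(rep: Replicon) -> tuple[float, float]:
    """(left_arm_bp, right_arm_bp) with validation for the dosage model."""
    if rep.ori_bp is None:
        raise ValueError(f"replicon {rep.name!r}: ori_bp required for simulation")
    if not rep.circular and rep.ori_bp not in (0, rep.length_bp):
        raise ValueError(
            f"replicon {rep.name!r}: non-circular replicon needs ori at an end"
        )
    return rep.arm_lengths()


def sim_copy_number(
    replicons: list[Replicon],
    growth: GrowthParams,
    window_bp: int,
    deletion: tuple[str, int, int] | None = None,
) -> ExpectedDosage:
    """Expected exponential-phase dosage profile.

    Per window at relative replication distance ``d`` on an arm of
    length ``A``: raw dosage ``2**(c_eff * (1 - d))`` with
    ``c_eff = c_over_tau * A / A_ref`` under co-termination (``A_ref``
    the longest arm of any replicon) and ``c_eff = c_over_tau``
    otherwise.  The profile is rescaled to mean 1 over non-deleted
    windows; deleted windows are exactly 0.
    """
    if not replicons:
        raise ValueError("no replicons")
    arms = {r.name: _arm_geometry(r) for r in replicons}
    ref_arm = max(max(a) for a in arms.values())
    frames = []
    for rep in replicons:
        starts, ends = tile_windows(rep.length_bp, window_bp)
        left_arm, right_arm = arms[rep.name]
        for arm in (left_arm, right_arm):
            if arm > 0 and arm / window_bp < 4:
                raise ValueError(
                    f"replicon {rep.name!r}: fewer than 4 windows per arm"
                )
        mid = (starts + ends) / 2.0
        dist = np.mod(mid - rep.ori_bp, rep.length_bp) if rep.circular else np.abs(
            mid - rep.ori_bp
        )
        on_right = dist <= right_arm if right_arm > 0 else np.zeros_like(dist, bool)
        with np.errstate(divide="ignore", invalid="ignore"):
            d_rel = np.where(
                on_right,
                dist / max(right_arm, 1e-300),
                (rep.length_bp - dist) / max(left_arm, 1e-300),
            )
        arm_len = np.where(on_right, right_arm, left_arm)
        if growth.co_terminate:
            c_eff = growth.c_over_tau * arm_len / ref_arm
        else:
            c_eff = np.full_like(arm_len, growth.c_over_tau)
        dosage = 2.0 ** (c_eff * (1.0 - np.clip(d_rel, 0.0, 1.0)))
        frames.append(
            pd.DataFrame(
                {"replicon": rep.name, "start": starts, "end": ends, "dosage": dosage}
            )
        )
    df = pd.concat(frames, ignore_index=True)
    if deletion is not None:
        name, s, e = deletion
        hit = (df["replicon"] == name) & (df["end"] > s) & (df["start"] < e)
        df.loc[hit, "dosage"] = 0.0
    live = df["dosage"] > 0
    df["dosage"] = df["dosage"] / df.loc[live, "dosage"].mean()
    return ExpectedDosage(df, window_bp, tuple(replicons), deletion)


def sim_read_windows(
    dosage: ExpectedDosage,
    total_reads: int,
    dispersion: float = 0.0,
    seed: int = 0,
) -> tuple[WindowCounts, WindowCounts]:
    """Draw paired exponential/stationary window counts.

    Exponential counts follow the dosage profile; stationary counts are
    uniform over non-deleted windows.  ``total_reads`` are distributed
    multinomially per sample.  With ``dispersion`` > 0 each window's
    weight is multiplied by a gamma-distributed bias factor (shape
    ``1/dispersion``, mean 1) representing window-specific library bias
    — mappability, GC content, fragmentation preference.  Such bias is
    reproducible between libraries prepared from the same reference, so
    the factor is shared by the two phases (it is exactly what dividing
    by the stationary sample cancels), while the read-sampling noise
    itself remains independent per phase.  Marginally each count is
    negative-binomial with variance ``m + dispersion * m**2``.
    """
    if total_reads <= 0:
        raise ValueError("total_reads must be > 0")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    rng = np.random.default_rng(seed)
    base = dosage.df[["replicon", "start", "end"]]
    bias = (
        rng.gamma(1.0 / dispersion, dispersion, size=len(base))
        if dispersion > 0
        else np.ones(len(base))
    )
    out = []
    for phase, weights in (
        ("exponential", dosage.values()),
        ("stationary", (dosage.values() > 0).astype(float)),
    ):
        w = weights.astype(float) * bias
        counts = rng.multinomial(total_reads, w / w.sum())
        df = base.copy()
        df["count"] = counts
        out.append(WindowCounts(df, dosage.window_bp, phase))
    return out[0], out[1]


def inject_artifacts(
    counts: WindowCounts,
    repeat_artifacts: list[tuple[str, int, int, float]],
) -> WindowCounts:
    """Multiply counts inside collapsed-repeat intervals.

    A collapsed repeat attracts the reads of all its genomic copies, so
    affected windows are inflated by the copy multiplier in *both*
    growth phases (apply this to each phase).  Overlapping artifacts
    compose multiplicatively.  Counts are rounded back to integers.
    """
    df = counts.df.copy()
    mult = np.ones(len(df))
    for name, s, e, m in repeat_artifacts:
        if m <= 0:
            raise ValueError("artifact multiplier must be > 0")
        hit = (df["replicon"] == name) & (df["end"] > s) & (df["start"] < e)
        if not hit.any():
            raise ValueError(f"artifact [{s}, {e}) hits no window on {name!r}")
        mult[hit.to_numpy()] *= m
    df["count"] = np.rint(df["count"].to_numpy() * mult).astype(np.int64)
    return WindowCounts(df, counts.window_bp, counts.phase)


def simulate_mfa_dataset(
    config: SimConfig,
) -> tuple[WindowCounts, WindowCounts, ExpectedDosage]:
    """End-to-end: dosage -> counts -> artifacts, per the config."""
    dosage = sim_copy_number(
        list(config.replicons), config.growth, config.window_bp, config.deletion
    )
    exp, stat = sim_read_windows(
        dosage, config.total_reads, config.dispersion, config.seed
    )
    if config.repeat_artifacts:
        exp = inject_artifacts(exp, list(config.repeat_artifacts))
        stat = inject_artifacts(stat, list(config.repeat_artifacts))
    return exp, stat, dosage


def ground_truth(config: SimConfig) -> dict:
    """True parameters implied by a config, for parameter-recovery tests."""
    arms = {r.name: _arm_geometry(r) for r in config.replicons}
    ref_arm = max(max(a) for a in arms.values())
    per_rep = {}
    for rep in config.replicons:
        arm = max(arms[rep.name])
        c_eff = (
            config.growth.c_over_tau * arm / ref_arm
            if config.growth.co_terminate
            else config.growth.c_over_tau
        )
        per_rep[rep.name] = {
            "ori_bp": rep.ori_bp,
            "ter_bp": rep.ter,
            "c_eff": c_eff,
            "ori_ter_ratio": 2.0**c_eff,
            "slope_log2_per_mb": c_eff / (arm / 1e6) if arm > 0 else 0.0,
        }
    lengths = {r.name: r.length_bp for r in config.replicons}
    order = sorted(per_rep, key=lambda n: -lengths[n])
    truth = {"replicons": per_rep, "deletion": config.deletion}
    if len(order) >= 2:
        truth["primary"] = order[0]
        truth["secondary"] = order[1]
        truth["initiation_delay_log2"] = (
            per_rep[order[0]]["c_eff"] - per_rep[order[1]]["c_eff"]
        )
    return truth


# ---------------------------------------------------------------------------
# kinetic curves


def sim_kinetic_curve(
    baseline: float,
    amplitude: float,
    rate: float,
    lag: float,
    timestep: float,
    horizon: float,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> KineticSeries:
    """Noisy logistic OD trace sampled every ``timestep`` minutes.

    ``lag`` is the logistic midpoint (minutes); the maximum slope of the
    noiseless curve is ``amplitude * rate / 4``.
    """
    if timestep <= 0:
        raise ValueError("timestep must be > 0")
    if not horizon > lag >= 0:
        raise ValueError("need horizon > lag >= 0")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, horizon + 0.5 * timestep, timestep)
    v = logistic(t, baseline, amplitude, rate, lag)
    if noise_sd > 0:
        v = v + rng.normal(0.0, noise_sd, size=t.size)
    return KineticSeries(t, v)


# ---------------------------------------------------------------------------
# competition assays


@dataclass(frozen=True)
class CompetitionCount:
    """Abundance counts for one competition assay.

    Final counts are in units comparable to the initial ones (event
    counts rescaled by the measured total expansion of the co-culture):
    the fitness formula is a ratio of log fold-changes of *absolute*
    numbers, and raw fixed-total cytometry proportions alone would not
    carry the growth information it needs.
    """

    n_initial_untagged: float
    n_final_untagged: float
    n_initial_tagged: float
    n_final_tagged: float


@dataclass(frozen=True)
class CompetitionAssay:
    """Sampled counts plus the noiseless expectation (for exact tests)."""

    sampled: CompetitionCount
    expected: CompetitionCount
    s: float
    generations: float


def sim_competition(
    s: float,
    generations: float = 8.64,
    events_per_read: int = 30_000,
    seed: int = 0,
) -> CompetitionAssay:
    """Simulate a 1:1 competition read out by flow cytometry.

    The untagged strain grows at relative rate ``1 + s`` versus the
    tagged reference; over ``generations`` reference doublings the true
    abundances change by ``2**(generations*(1+s))`` and
    ``2**generations``.  Initial and final compositions are read by
    drawing ``events_per_read`` events binomially from the true
    proportions; final counts are then rescaled by the total expansion
    of the co-culture (known from the dilution regime) so that they are
    proportional to absolute abundance — the form the fitness formula
    requires.  The default 8.64 generations corresponds to a 1:400
    dilution regrown to saturation; 30,000 events per read is the usual
    cytometer setting.
    """
    if s <= -1:
        raise ValueError("selection coefficient must be > -1")
    if events_per_read <= 0:
        raise ValueError("events_per_read must be > 0")
    rng = np.random.default_rng(seed)
    p0 = 0.5
    fu = 2.0 ** (generations * (1.0 + s))
    ft = 2.0**generations
    total_growth = p0 * fu + (1 - p0) * ft
    pf = p0 * fu / total_growth
    xi = rng.binomial(events_per_read, p0)
    xf = rng.binomial(events_per_read, pf)
    sampled = CompetitionCount(
        xi,
        xf * total_growth,
        events_per_read - xi,
        (events_per_read - xf) * total_growth,
    )
    expected = CompetitionCount(
        events_per_read * p0,
        events_per_read * pf * total_growth,
        events_per_read * (1 - p0),
        events_per_read * (1 - pf) * total_growth,
    )
    return CompetitionAssay(sampled, expected, s, generations)


# ---------------------------------------------------------------------------
# kill curves


@dataclass(frozen=True)
class KillCurve:
    """CFU/ml over time under antibiotic exposure; rows are replicates."""

    timepoints_h: np.ndarray
    cfu_per_ml: np.ndarray  # shape (n_replicates, n_timepoints)

    def __post_init__(self) -> None:
        t = np.asarray(self.timepoints_h, dtype=float)
        c = np.atleast_2d(np.asarray(self.cfu_per_ml, dtype=float))
        if t.size == 0:
            raise ValueError("empty timepoints")
        if not np.all(np.diff(t) > 0):
            raise ValueError("timepoints must be strictly increasing")
        if c.shape[1] != t.size:
            raise ValueError("cfu_per_ml shape does not match timepoints")
        if (c < 0).any():
            raise ValueError("negative CFU")
        object.__setattr__(self, "timepoints_h", t)
        object.__setattr__(self, "cfu_per_ml", c)


def kill_curve_expected(
    initial_cfu: float,
    kill_rate: float,
    persister_fraction: float,
    persister_kill_rate: float,
    timepoints: np.ndarray,
) -> np.ndarray:
    """Noiseless biphasic decay: a sensitive bulk dying at ``kill_rate``
    (per hour) plus a persister subpopulation dying at
    ``persister_kill_rate``."""
    if not 0 <= persister_fraction <= 1:
        raise ValueError("persister_fraction must be in [0, 1]")
    if kill_rate < 0 or persister_kill_rate < 0:
        raise ValueError("kill rates must be >= 0")
    t = np.asarray(timepoints, dtype=float)
    if t.size == 0:
        raise ValueError("empty timepoints")
    f = persister_fraction
    return initial_cfu * (
        (1 - f) * np.exp(-kill_rate * t) + f * np.exp(-persister_kill_rate * t)
    )


def sim_kill_curve(
    initial_cfu: float,
    kill_rate: float,
    persister_fraction: float,
    persister_kill_rate: float,
    timepoints: np.ndarray,
    seed: int = 0,
) -> KillCurve:
    """One replicate of a biphasic kill curve with Poisson CFU noise."""
    mean = kill_curve_expected(
        initial_cfu, kill_rate, persister_fraction, persister_kill_rate, timepoints
    )
    rng = np.random.default_rng(seed)
    cfu = rng.poisson(mean).astype(float)
    return KillCurve(np.asarray(timepoints, dtype=float), cfu[None, :])


# ---------------------------------------------------------------------------
# configuration


def default_study_config(seed: int = 0, **overrides) -> SimConfig:
    """The two-chromosome study condition: a 3.0 Mb primary and a
    1.07 Mb secondary circular chromosome, co-terminating, one round of
    overlapping replication (``c_over_tau=1``), 2x10^6 reads per phase,
    dispersion 0.02, 1 kb windows."""
    params = dict(
        replicons=(
            Replicon("chr1", 3_000_000, True, ori_bp=1_200_000),
            Replicon("chr2", 1_070_000, True, ori_bp=300_000),
        ),
        growth=GrowthParams(c_over_tau=1.0, co_terminate=True),
        total_reads=2_000_000,
        dispersion=0.02,
        window_bp=1_000,
        seed=seed,
    )
    params.update(overrides)
    return SimConfig(**params)


def load_sim_config(path) -> SimConfig:
    """Read a YAML file mapping 1:1 to :class:`SimConfig`."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    replicons = tuple(
        Replicon(
            r["name"],
            int(r["length_bp"]),
            bool(r.get("circular", True)),
            r.get("ori_bp"),
            r.get("ter_bp"),
        )
        for r in raw["replicons"]
    )
    growth = GrowthParams(**raw.get("growth", {}))
    return SimConfig(
        replicons=replicons,
        growth=growth,
        total_reads=int(raw.get("total_reads", 2_000_000)),
        dispersion=float(raw.get("dispersion", 0.02)),
        window_bp=int(raw.get("window_bp", 1_000)),
        repeat_artifacts=tuple(
            (a["replicon"], int(a["start"]), int(a["end"]), float(a["multiplier"]))
            for a in raw.get("repeat_artifacts", [])
        ),
        deletion=(
            (
                raw["deletion"]["replicon"],
                int(raw["deletion"]["start"]),
                int(raw["deletion"]["end"]),
            )
            if raw.get("deletion")
            else None
        ),
        seed=int(raw.get("seed", 0)),
    )
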