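"""Marker frequency analysis (MFA).

MFA infers chromosome replication dynamics from sequencing coverage: in
exponentially growing bacteria, loci near the replication origin are
present in more copies per cell than loci near the terminus, so read
depth along each chromosome traces an inverted "V" peaking at *ori*.
Dividing exponential-phase window counts by stationary-phase counts
cancels locus-specific mapping bias (the stationary culture has uniform
copy number), and the log2 profile is piecewise linear in genomic
position.  From the fitted V one reads off the origin position, the
per-arm replication slopes, the ori:ter copy-number ratio, and — when
two chromosomes are analysed jointly — the relative timing of their
initiation.

Pipeline: :func:`aggregate_windows` -> :func:`normalize_mfa` ->
:func:`exclude_windows` -> :func:`center_on_origin` ->
:func:`fit_replication`, with :func:`detect_gaps` (deletions appear as
runs of zero-coverage windows) and :func:`detect_slope_breaks`
(rearrangements appear as local slope inconsistencies) as companions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import Replicon, signed_offset, tile_windows, circular_distance

__all__ = [
    "WindowCounts",
    "MFAProfile",
    "RepliconFit",
    "ReplicationFit",
    "DeletionCall",
    "SlopeBreak",
    "aggregate_windows",
    "rebin",
    "normalize_mfa",
    "exclude_windows",
    "center_on_origin",
    "fit_replication",
    "detect_gaps",
    "detect_slope_breaks",
]

_COLS = ["replicon", "start", "end", "count"]


@dataclass(frozen=True)
class WindowCounts:
    """Read-start counts per fixed-size window for one sample phase.

    ``df`` has columns ``replicon, start, end, count``; windows tile each
    replicon without overlap, in ascending order, with at most one
    trailing partial window.
    """

    df: pd.DataFrame
    window_bp: int
    phase: str = "exponential"

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True)
        missing = [c for c in _COLS if c not in df.columns]
        if missing:
            raise ValueError(f"WindowCounts missing columns {missing}")
        if (df["count"] < 0).any():
            raise ValueError("negative counts")
        for name, sub in df.groupby("replicon", sort=False):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if starts[0] != 0 or not np.array_equal(starts[1:], ends[:-1]):
                raise ValueError(f"windows do not tile replicon {name!r}")
            if np.any((ends - starts)[:-1] != self.window_bp):
                raise ValueError(f"non-uniform window size on replicon {name!r}")
        object.__setattr__(self, "df", df)

    def counts(self) -> np.ndarray:
        return self.df["count"].to_numpy(dtype=float)

    def midpoints(self) -> np.ndarray:
        return ((self.df["start"] + self.df["end"]) // 2).to_numpy(dtype=np.int64)

    def same_grid(self, other: "WindowCounts") -> bool:
        a, b = self.df, other.df
        return (
            len(a) == len(b)
            and a["replicon"].equals(b["replicon"])
            and a["start"].equals(b["start"])
            and a["end"].equals(b["end"])
        )


def aggregate_windows(
    per_base_starts: dict[str, np.ndarray],
    replicons: list[Replicon],
    window_bp: int,
    phase: str = "exponential",
) -> WindowCounts:
    """Count read-start positions into fixed windows.

    ``per_base_starts`` maps replicon name to an array of 0-based read
    start positions.  A window ``[s, s+w)`` counts starts with
    ``s <= pos < s+w``; the trailing partial window is kept.
    """
    frames = []
    known = {r.name: r for r in replicons}
    for name in per_base_starts:
        if name not in known:
            raise ValueError(f"unknown replicon {name!r}; known: {sorted(known)}")
    for rep in replicons:
        starts, ends = tile_windows(rep.length_bp, window_bp)
        pos = np.asarray(per_base_starts.get(rep.name, []), dtype=np.int64)
        if pos.size and (pos.min() < 0 or pos.max() >= rep.length_bp):
            raise ValueError(
                f"read start position outside replicon {rep.name!r} "
                f"(length {rep.length_bp})"
            )
        n = np.bincount(pos // window_bp, minlength=starts.size)
        frames.append(
            pd.DataFrame(
                {"replicon": rep.name, "start": starts, "end": ends, "count": n}
            )
        )
    return WindowCounts(pd.concat(frames, ignore_index=True), window_bp, phase)


def rebin(counts: WindowCounts, window_bp: int) -> WindowCounts:
    """Re-aggregate to a coarser grid; ``window_bp`` must be a multiple
    of the current window size.  Counts of member windows are summed."""
    if window_bp % counts.window_bp != 0:
        raise ValueError("new window size must be a multiple of the current one")
    frames = []
    for name, sub in counts.df.groupby("replicon", sort=False):
        new_start = (sub["start"] // window_bp) * window_bp
        agg = sub.groupby(new_start)["count"].sum()
        ends_by_start = sub.groupby(new_start)["end"].max()
        frames.append(
            pd.DataFrame(
                {
                    "replicon": name,
                    "start": agg.index.to_numpy(),
                    "end": np.minimum(
                        agg.index.to_numpy() + window_bp, ends_by_start.to_numpy()
                    ),
                    "count": agg.to_numpy(),
                }
            )
        )
    return WindowCounts(pd.concat(frames, ignore_index=True), window_bp, counts.phase)


# ---------------------------------------------------------------------------
# normalization

REASON_NONE = ""
REASON_ZERO_STAT = "zero-stationary"
REASON_REPEAT = "repeat-like"
REASON_PARTIAL = "partial"
REASON_DELETION = "deletion"


@dataclass(frozen=True)
class MFAProfile:
    """Normalized ori-centred dosage profile.

    ``df`` columns: ``replicon, start, end, frequency, ori_distance,
    included, reason``.  The mean of ``frequency`` over included windows
    of all replicons is 1; excluded windows carry a reason tag and a
    frequency computed with the same factors (NaN where undefined).
    """

    df: pd.DataFrame
    window_bp: int

    def included_mask(self) -> np.ndarray:
        return self.df["included"].to_numpy(dtype=bool)

    def check_mean_one(self, tol: float = 1e-9) -> bool:
        inc = self.included_mask()
        return bool(abs(self.df.loc[inc, "frequency"].mean() - 1.0) <= tol)


def _partial_mask(df: pd.DataFrame, window_bp: int) -> np.ndarray:
    return ((df["end"] - df["start"]) != window_bp).to_numpy()


def normalize_mfa(exp: WindowCounts, stat: WindowCounts) -> MFAProfile:
    """Normalize exponential counts by the stationary reference.

    Per window *i*, the stationary sample defines a correction factor
    ``factor_i = stat_i / mean(stat | included)`` — the deviation of the
    observed from the expected (uniform) stationary count.  The
    exponential count is divided by this factor and the corrected values
    are rescaled to mean 1 over included windows of all replicons
    jointly, so that the relative dosage of co-analysed chromosomes is
    preserved.  Windows with a zero stationary count cannot be corrected
    and are excluded; partial trailing windows are flagged and excluded
    from the mean.
    """
    if not exp.same_grid(stat):
        raise ValueError("exponential and stationary samples are on different grids")
    s = stat.counts()
    e = exp.counts()
    if not np.any(s > 0):
        raise ValueError("all-zero stationary sample")

    reason = np.full(len(s), REASON_NONE, dtype=object)
    reason[_partial_mask(exp.df, exp.window_bp)] = REASON_PARTIAL
    reason[s == 0] = REASON_ZERO_STAT
    included = reason == REASON_NONE

    freq = _renormalize(e, s, included)
    df = exp.df[["replicon", "start", "end"]].copy()
    df["frequency"] = freq
    df["ori_distance"] = np.nan
    df["included"] = included
    df["reason"] = reason
    return MFAProfile(df, exp.window_bp)


def _renormalize(e: np.ndarray, s: np.ndarray, included: np.ndarray) -> np.ndarray:
    """factor-divide then rescale to mean 1 over the included windows."""
    factor = s / s[included].mean()
    with np.errstate(divide="ignore", invalid="ignore"):
        corrected = np.where(factor > 0, e / np.where(factor > 0, factor, 1.0), np.nan)
    return corrected / corrected[included].mean()


def exclude_windows(
    profile: MFAProfile, stat: WindowCounts, log2_threshold: float = 1.0
) -> MFAProfile:
    """Mark repeat-like windows and re-normalize.

    A window whose stationary count deviates from the stationary mean
    (over currently included windows) by more than ``log2_threshold`` in
    absolute log2 is flagged ``repeat-like``: collapsed repeats inflate
    coverage in both phases and must not enter the fit.  Frequencies are
    re-scaled so the mean over the surviving windows is 1 again (the
    stationary factor itself is scale-free, so only the mean-1 rescaling
    changes).
    """
    if log2_threshold <= 0:
        raise ValueError("log2_threshold must be > 0")
    if len(profile.df) != len(stat.df):
        raise ValueError("profile and stationary sample are on different grids")
    df = profile.df.copy()
    included = df["included"].to_numpy(dtype=bool)
    reason = df["reason"].to_numpy(dtype=object).copy()
    s = stat.counts()
    mean_s = s[included].mean()
    with np.errstate(divide="ignore"):
        dev = np.abs(np.log2(np.where(s > 0, s / mean_s, np.inf)))
    repeat_like = included & ((dev > log2_threshold) | (s == 0))
    reason[repeat_like] = REASON_REPEAT
    included = included & ~repeat_like

    freq = df["frequency"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        freq = freq / np.nanmean(freq[included])
    df["frequency"] = freq
    df["included"] = included
    df["reason"] = reason
    return MFAProfile(df, profile.window_bp)


def center_on_origin(profile: MFAProfile, replicons: list[Replicon]) -> MFAProfile:
    """Attach signed ori-centred offsets (in ``(-L/2, L/2]``) to windows."""
    by_name = {r.name: r for r in replicons}
    df = profile.df.copy()
    dist = np.full(len(df), np.nan)
    for name, sub in df.groupby("replicon", sort=False):
        rep = by_name.get(name)
        if rep is None:
            raise ValueError(f"no metadata for replicon {name!r}")
        if rep.ori_bp is None:
            raise ValueError(f"replicon {name!r} has no origin set")
        mid = ((sub["start"] + sub["end"]) // 2).to_numpy()
        dist[sub.index] = signed_offset(mid, rep.ori_bp, rep.length_bp, rep.circular)
    df["ori_distance"] = dist
    return MFAProfile(df, profile.window_bp)


# ---------------------------------------------------------------------------
# replication fit


@dataclass(frozen=True)
class RepliconFit:
    """Fitted inverted-V replication parameters for one replicon.

    Slopes are in log2 frequency per Mb; the left arm ascends towards
    the origin (slope >= 0 in signed coordinates) and the right arm
    descends (slope <= 0).  ``ori_ter_ratio = 2**(ori_height - ter_height)``
    on the fitted V.  ``no_gradient`` is set when both arm slopes fall
    below the noise floor, in which case the ratio is reported as 1 and
    no origin is invented.
    """

    replicon: str
    ori_hat_bp: float | None
    ter_hat_bp: float | None
    slope_left: float
    slope_right: float
    slope_se_left: float
    slope_se_right: float
    r2_left: float
    r2_right: float
    ori_height_log2: float
    ter_height_log2: float
    ori_ter_ratio: float
    n_windows: int
    no_gradient: bool


@dataclass(frozen=True)
class ReplicationFit:
    """Per-replicon fits plus cross-replicon initiation timing.

    ``initiation_delay_log2`` is the fitted log2 ori-height of the
    primary (longest) replicon minus that of the secondary; on a joint
    mean-1 profile this equals the difference in replication exponents,
    and multiplied by the doubling time it is the delay, in minutes,
    with which the secondary chromosome fires its origin.
    """

    replicons: dict[str, RepliconFit]
    primary: str | None = None
    secondary: str | None = None
    initiation_delay_log2: float | None = None
    initiation_delay_min: float | None = None


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares line: returns (intercept, slope, sse)."""
    n = x.size
    if n == 0:
        return np.nan, 0.0, 0.0
    xm = x.mean()
    ym = y.mean()
    sxx = float(((x - xm) ** 2).sum())
    if sxx == 0.0 or n < 2:
        return ym, 0.0, float(((y - ym) ** 2).sum())
    b = float(((x - xm) * (y - ym)).sum()) / sxx
    a = ym - b * xm
    resid = y - (a + b * x)
    return a, b, float((resid**2).sum())


def _hinge_fit(d: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Continuous inverted-V regression with the apex pinned at d = 0.

    Fits ``y = a + bL*d`` for d < 0 and ``y = a + bR*d`` for d >= 0 with
    a shared apex height ``a`` and the slope signs constrained to
    (bL >= 0, bR <= 0).  Returns ``(a, bL, bR, sse)``.  The continuity
    constraint is what localizes the apex: with free intercepts the
    total squared error is nearly flat in the apex position.
    """
    left = d < 0
    x1 = np.where(left, d, 0.0)
    x2 = np.where(left, 0.0, d)
    n = d.size
    Sy = y.sum()
    S1, S2 = x1.sum(), x2.sum()
    Q1, Q2 = (x1**2).sum(), (x2**2).sum()
    P1, P2 = (x1 * y).sum(), (x2 * y).sum()
    Syy = (y**2).sum()

    def _sse(a, bL, bR):
        return float(
            Syy
            + a * a * n
            + bL * bL * Q1
            + bR * bR * Q2
            - 2 * a * Sy
            - 2 * bL * P1
            - 2 * bR * P2
            + 2 * a * (bL * S1 + bR * S2)
        )

    candidates = []
    # unconstrained optimum
    den = n - (S1 * S1 / Q1 if Q1 > 0 else 0.0) - (S2 * S2 / Q2 if Q2 > 0 else 0.0)
    if den > 0:
        a = (
            Sy
            - (S1 * P1 / Q1 if Q1 > 0 else 0.0)
            - (S2 * P2 / Q2 if Q2 > 0 else 0.0)
        ) / den
        bL = (P1 - a * S1) / Q1 if Q1 > 0 else 0.0
        bR = (P2 - a * S2) / Q2 if Q2 > 0 else 0.0
        if bL >= 0 and bR <= 0:
            candidates.append((a, bL, bR))
    # bL pinned at 0: simple regression on x2
    det2 = n * Q2 - S2 * S2
    if det2 > 0:
        a = (Sy * Q2 - S2 * P2) / det2
        bR = (n * P2 - S2 * Sy) / det2
        if bR <= 0:
            candidates.append((a, 0.0, bR))
    # bR pinned at 0: simple regression on x1
    det1 = n * Q1 - S1 * S1
    if det1 > 0:
        a = (Sy * Q1 - S1 * P1) / det1
        bL = (n * P1 - S1 * Sy) / det1
        if bL >= 0:
            candidates.append((a, bL, 0.0))
    # both slopes pinned: flat line
    candidates.append((Sy / n, 0.0, 0.0))
    a, bL, bR = min(candidates, key=lambda c: _sse(*c))
    return float(a), float(bL), float(bR), max(_sse(a, bL, bR), 0.0)


def _closed_v_fit(
    u: np.ndarray, y: np.ndarray, length_mb: float, max_iter: int = 5
) -> tuple[float, float, float, float, np.ndarray]:
    """Continuous V closed on the circle, apex at ``u = 0``.

    ``u`` is the clockwise offset from the candidate origin in
    ``[0, L)``.  The right arm is ``a + bR*u`` and the left arm
    ``a + bL*(u - L)``; the two lines cross at the terminus
    ``u_t = bL*L/(bL - bR)``, and windows are assigned to the arm whose
    line covers them.  The assignment depends on the slopes, so it is
    iterated from the antipodal split until stable.  Closure matters:
    it pins both ends of each arm line, so a misplaced apex cannot be
    absorbed by tilting the arms, and the apex search retains its full
    statistical power.

    Returns ``(a, bL, bR, sse, d)`` where ``d`` is the signed arm
    coordinate actually used (``u`` on the right arm, ``u - L`` on the
    left).
    """
    right = u <= length_mb / 2.0
    a = bL = bR = 0.0
    sse = np.inf
    d = np.where(right, u, u - length_mb)
    for _ in range(max_iter):
        d = np.where(right, u, u - length_mb)
        a, bL, bR, sse = _hinge_fit(d, y)
        if bL - bR <= 0:
            break
        u_t = bL * length_mb / (bL - bR)
        new_right = u <= u_t
        if np.array_equal(new_right, right):
            break
        right = new_right
    return a, bL, bR, sse, d


def _symmetric_v_sse(u: np.ndarray, y: np.ndarray, length_mb: float) -> float:
    """SSE of the symmetric V (equal |slopes|, valley at the antipode)."""
    r = np.minimum(u, length_mb - u)
    rm = r.mean()
    ym = y.mean()
    sxx = float(((r - rm) ** 2).sum())
    b = float(((r - rm) * (y - ym)).sum()) / sxx if sxx > 0 else 0.0
    b = min(b, 0.0)  # dosage cannot rise away from the origin
    a = ym - b * rm
    return float(((y - a - b * r) ** 2).sum())


def _fit_replicon(
    mid_mb: np.ndarray,
    logf: np.ndarray,
    length_mb: float,
    annotated_ori_mb: float | None,
    symmetric_apex: bool = True,
) -> int:
    """Exhaustive grid search of the V apex over window midpoints.

    With ``symmetric_apex`` the search assumes equal fork speeds (equal
    and opposite arm slopes, terminus antipodal), which pins both arms
    and localizes the apex most sharply; slopes are refit freely at the
    chosen apex afterwards.  Without it the asymmetric closed V is
    scored at every candidate.
    """
    n = mid_mb.size
    sses = np.empty(n)
    for k in range(n):
        u = np.mod(mid_mb - mid_mb[k], length_mb)
        if symmetric_apex:
            sses[k] = _symmetric_v_sse(u, logf, length_mb)
        else:
            sses[k] = _closed_v_fit(u, logf, length_mb)[3]
    best_sse = sses.min()
    # tie-break: among near-optimal candidates prefer the annotated ori,
    # else the lowest coordinate
    tol = 1e-12 * max(1.0, best_sse)
    ties = np.flatnonzero(sses <= best_sse + tol)
    if annotated_ori_mb is not None and ties.size > 1:
        k_best = ties[
            np.argmin(circular_distance(mid_mb[ties], annotated_ori_mb, length_mb))
        ]
    else:
        k_best = ties[np.argmin(mid_mb[ties])] if ties.size > 1 else ties[0]
    return int(k_best)


def fit_replication(
    profile: MFAProfile,
    replicons: list[Replicon],
    doubling_time: float | None = None,
    slope_floor: float = 0.05,
    min_windows: int = 10,
    symmetric_apex: bool = True,
) -> ReplicationFit:
    """Fit the inverted-V replication model per replicon.

    The candidate origin is searched exhaustively over included window
    midpoints, scoring at each candidate a continuous inverted V in
    log2(frequency) versus origin offset (Mb) — by default the
    symmetric V (equal fork speeds), see :func:`_fit_replicon`.  At the
    winning candidate the two arm slopes are refit freely with their
    signs enforced and the apex height shared (:func:`_closed_v_fit`);
    the terminus is where the two arm lines cross on the far side of
    the circle.  When both arm slopes are below ``slope_floor``
    (log2/Mb) the profile is flat (stationary-like): the fit returns
    ``no_gradient=True`` with ratio 1 rather than an arbitrary origin.
    """
    by_name = {r.name: r for r in replicons}
    fits: dict[str, RepliconFit] = {}
    for name, sub in profile.df.groupby("replicon", sort=False):
        rep = by_name.get(name)
        if rep is None:
            raise ValueError(f"no metadata for replicon {name!r}")
        inc = sub["included"].to_numpy(dtype=bool)
        freq = sub["frequency"].to_numpy(dtype=float)
        usable = inc & np.isfinite(freq) & (freq > 0)
        if usable.sum() < min_windows:
            raise ValueError(
                f"replicon {name!r}: {int(usable.sum())} usable windows "
                f"(need >= {min_windows})"
            )
        mid = ((sub["start"] + sub["end"]) // 2).to_numpy(dtype=float)[usable]
        logf = np.log2(freq[usable])
        length_mb = rep.length_bp / 1e6
        mid_mb = mid / 1e6
        ori_mb = None if rep.ori_bp is None else rep.ori_bp / 1e6

        k = _fit_replicon(mid_mb, logf, length_mb, ori_mb, symmetric_apex)
        cand = mid_mb[k]
        u = np.mod(mid_mb - cand, length_mb)
        a, bL, bR, sse, d = _closed_v_fit(u, logf, length_mb)

        fits[name] = _summarize_arms(rep, cand, d, logf, a, bL, bR, sse, slope_floor)

    primary = secondary = None
    delay = delay_min = None
    graded = [f for f in fits.values() if not f.no_gradient]
    if len(fits) >= 2:
        order = sorted(fits, key=lambda n: -by_name[n].length_bp)
        primary, secondary = order[0], order[1]
        fp, fs = fits[primary], fits[secondary]
        if not fp.no_gradient and not fs.no_gradient:
            delay = fp.ori_height_log2 - fs.ori_height_log2
            if doubling_time is not None:
                delay_min = delay * doubling_time
    return ReplicationFit(fits, primary, secondary, delay, delay_min)


def _summarize_arms(rep, cand_mb, d, logf, a, bL, bR, sse, slope_floor) -> RepliconFit:
    length_mb = rep.length_bp / 1e6
    left = d < 0
    n = d.size
    resid = logf - (a + np.where(left, bL, bR) * d)
    sseL = float((resid[left] ** 2).sum())
    sseR = float((resid[~left] ** 2).sum())

    # slope standard errors from the joint (a, bL, bR) covariance
    x1 = np.where(left, d, 0.0)
    x2 = np.where(left, 0.0, d)
    xtx = np.array(
        [
            [n, x1.sum(), x2.sum()],
            [x1.sum(), (x1**2).sum(), 0.0],
            [x2.sum(), 0.0, (x2**2).sum()],
        ]
    )
    seL = seR = np.nan
    if n > 3:
        sigma2 = sse / (n - 3)
        try:
            cov = sigma2 * np.linalg.inv(xtx)
            seL, seR = np.sqrt(cov[1, 1]), np.sqrt(cov[2, 2])
        except np.linalg.LinAlgError:
            pass

    def _r2(sse_arm, y):
        if y.size == 0:
            return np.nan
        tss = float(((y - y.mean()) ** 2).sum())
        return 1.0 - sse_arm / tss if tss > 0 else 1.0

    no_gradient = max(abs(bL), abs(bR)) < slope_floor
    if no_gradient:
        return RepliconFit(
            replicon=rep.name,
            ori_hat_bp=None if rep.ori_bp is None else float(rep.ori_bp),
            ter_hat_bp=None,
            slope_left=bL,
            slope_right=bR,
            slope_se_left=seL,
            slope_se_right=seR,
            r2_left=_r2(sseL, logf[left]),
            r2_right=_r2(sseR, logf[~left]),
            ori_height_log2=float(logf.mean()),
            ter_height_log2=float(logf.mean()),
            ori_ter_ratio=1.0,
            n_windows=int(logf.size),
            no_gradient=True,
        )
    ori_height = a
    # terminus: where the descending right line meets the ascending left
    # line continued one full turn behind, at offset x in (0, L]
    if bR - bL != 0.0:
        x = -bL * length_mb / (bR - bL)
        if not 0.0 < x <= length_mb:
            x = length_mb / 2.0
    else:
        x = length_mb / 2.0
    ter_height = a + bR * x
    ori_bp = (cand_mb * 1e6) % rep.length_bp
    ter_bp = (ori_bp + x * 1e6) % rep.length_bp
    return RepliconFit(
        replicon=rep.name,
        ori_hat_bp=float(ori_bp),
        ter_hat_bp=float(ter_bp),
        slope_left=bL,
        slope_right=bR,
        slope_se_left=seL,
        slope_se_right=seR,
        r2_left=_r2(sseL, logf[left]),
        r2_right=_r2(sseR, logf[~left]),
        ori_height_log2=float(ori_height),
        ter_height_log2=float(ter_height),
        ori_ter_ratio=float(2.0 ** (ori_height - ter_height)),
        n_windows=int(logf.size),
        no_gradient=False,
    )


# ---------------------------------------------------------------------------
# gap and slope-break detection


@dataclass(frozen=True)
class DeletionCall:
    """A run of zero-coverage windows (candidate deletion)."""

    replicon: str
    start_bp: int
    end_bp: int
    n_windows: int
    phases_affected: str  # "exponential" or "both"


def detect_gaps(
    exp: WindowCounts, stat: WindowCounts | None = None, min_run: int = 5
) -> list[DeletionCall]:
    """Report maximal runs of >= ``min_run`` zero-count exponential windows.

    When the stationary sample is given, ``phases_affected`` records
    whether the run is zero there too ("both": reads truly missing, the
    signature of a deletion relative to the mapping reference) or only
    in exponential phase (a phase-specific artifact).
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    if stat is not None and not exp.same_grid(stat):
        raise ValueError("phases are on different grids")
    calls: list[DeletionCall] = []
    s = stat.counts() if stat is not None else None
    for name, sub in exp.df.groupby("replicon", sort=False):
        zero = (sub["count"].to_numpy() == 0).astype(int)
        # run-length encode
        edges = np.flatnonzero(np.diff(np.concatenate(([0], zero, [0]))))
        for a, b in zip(edges[::2], edges[1::2]):
            if b - a < min_run:
                continue
            idx = sub.index[a:b]
            both = s is not None and bool((s[idx] == 0).all())
            calls.append(
                DeletionCall(
                    replicon=name,
                    start_bp=int(sub["start"].iloc[a]),
                    end_bp=int(sub["end"].iloc[b - 1]),
                    n_windows=int(b - a),
                    phases_affected="both" if both else "exponential",
                )
            )
    return calls


@dataclass(frozen=True)
class SlopeBreak:
    """A local slope inconsistency in the inverted V (rearrangement signal)."""

    replicon: str
    position_bp: int
    pre_slope: float
    post_slope: float
    severity: float  # |local - arm slope| in units of the arm slope's SE


def detect_slope_breaks(
    profile: MFAProfile,
    fit: ReplicationFit,
    replicons: list[Replicon],
    window_span: int = 50,
    severity_threshold: float = 5.0,
) -> list[SlopeBreak]:
    """Scan each arm with sliding local regressions and flag spans whose
    slope is inconsistent with the fitted arm slope.

    Severity is ``|local slope - fitted arm slope|`` divided by the
    fitted arm slope's standard error.  Spans touching the ori or ter
    apex are skipped (the V bends there by construction), and flat
    (``no_gradient``) profiles yield no breaks.  Contiguous exceeding
    spans are merged into a single call at the peak-severity position.
    """
    by_name = {r.name: r for r in replicons}
    breaks: list[SlopeBreak] = []
    for name, sub in profile.df.groupby("replicon", sort=False):
        rfit = fit.replicons.get(name)
        if rfit is None or rfit.no_gradient or rfit.ori_hat_bp is None:
            continue
        rep = by_name[name]
        inc = sub["included"].to_numpy(dtype=bool)
        freq = sub["frequency"].to_numpy(dtype=float)
        usable = inc & np.isfinite(freq) & (freq > 0)
        mid = ((sub["start"] + sub["end"]) // 2).to_numpy(dtype=float)[usable]
        logf = np.log2(freq[usable])
        d = signed_offset(mid, rfit.ori_hat_bp, rep.length_bp, rep.circular) / 1e6
        order = np.argsort(d)
        d, logf, mid = d[order], logf[order], mid[order]
        for arm_mask, arm_slope, arm_se in (
            (d < 0, rfit.slope_left, rfit.slope_se_left),
            (d >= 0, rfit.slope_right, rfit.slope_se_right),
        ):
            da, ya, ma = d[arm_mask], logf[arm_mask], mid[arm_mask]
            n = da.size
            if n <= window_span:
                raise ValueError(
                    f"window_span {window_span} too large for arm of {n} windows"
                )
            margin = window_span // 2  # keep clear of the ori/ter apexes
            hits: list[tuple[int, float, float]] = []
            se = arm_se if np.isfinite(arm_se) and arm_se > 0 else 0.0
            # floor the unit so a numerically perfect fit does not turn
            # rounding error into infinite severity
            denom = max(se, 1e-9 * max(1.0, abs(arm_slope)))
            for i in range(margin, n - window_span - margin + 1):
                sl = slice(i, i + window_span)
                _, b, _ = _ols_line(da[sl], ya[sl])
                dev = abs(b - arm_slope)
                severity = dev / denom
                if severity > severity_threshold:
                    hits.append((i, severity, b))
            # merge contiguous hits into one break at peak severity
            run: list[tuple[int, float, float]] = []
            for h in hits + [(-10**9, 0.0, 0.0)]:
                if run and h[0] != run[-1][0] + 1:
                    peak = max(run, key=lambda t: t[1])
                    i0, i1 = run[0][0], run[-1][0]
                    breaks.append(
                        SlopeBreak(
                            replicon=name,
                            position_bp=int(ma[peak[0] + window_span // 2]),
                            pre_slope=run[0][2],
                            post_slope=run[-1][2],
                            severity=float(peak[1]),
                        )
                    )
                    run = []
                if h[0] >= 0:
                    run.append(h)
    return breaks
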