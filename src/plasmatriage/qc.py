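"""Fragment-size quality control for plasma cell-free DNA samples.

Plasma ccfDNA is dominated by mononucleosomal fragments peaking near 167 bp;
lysed-leukocyte (genomic) contamination appears as very long fragments
(> 2 kb). A sample is usable when it carries detectable signal in the
100-500 bp cfDNA window; samples with no material, or with only long
genomic fragments, are excluded before library preparation. Yield
comparisons between processing groups use classical t-tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

CFDNA_WINDOW = (100, 500)
LONG_FRAGMENT_CUTOFF_BP = 2000


@dataclass
class FragmentProfile:
    """Histogram of fragment length (bp) -> abundance for one sample.

    Abundance is unit-agnostic (electropherogram signal, molarity, or
    simulated fragment counts); only nonnegativity is assumed.
    """

    histogram: pd.Series  # index: length in bp, values: abundance
    sample_id: str = ""
    processing_delay_h: Optional[float] = None
    timepoint: Optional[str] = None  # pre-surgery | post-surgery

    def __post_init__(self) -> None:
        h = pd.Series(self.histogram, dtype=float).sort_index()
        if (h.values < 0).any():
            raise ValueError("abundances must be nonnegative")
        if len(h) and (h.index <= 0).any():
            raise ValueError("fragment lengths must be positive")
        self.histogram = h

    @property
    def total(self) -> float:
        return float(self.histogram.sum())

    def mass_above(self, cutoff_bp: float) -> float:
        return float(self.histogram[self.histogram.index > cutoff_bp].sum())


@dataclass
class QCThresholds:
    """Verdict thresholds; category exemplars, not absolutes, so configurable."""

    min_total_signal: float = 1.0
    min_window_signal: float = 1.0
    max_contaminant_fraction: float = 0.9
    long_cutoff_bp: float = LONG_FRAGMENT_CUTOFF_BP
    clean_contaminant_fraction: float = 0.05


@dataclass
class QCVerdict:
    status: str  # pass | fail
    reason: str  # no_material | genomic_contamination | clean | tolerable_contamination
    cfdna_window_yield: float

    @property
    def passed(self) -> bool:
        return self.status == "pass"


def quantify_window(profile: FragmentProfile, lo_bp: float = CFDNA_WINDOW[0],
                    hi_bp: float = CFDNA_WINDOW[1]) -> float:
    """Total abundance in the [lo_bp, hi_bp] fragment-size window (default 100-500)."""
    if lo_bp >= hi_bp:
        raise ValueError("window lower bound must be below upper bound")
    h = profile.histogram
    if h.empty:
        warnings.warn(f"empty fragment histogram for sample {profile.sample_id!r}")
        return 0.0
    mask = (h.index >= lo_bp) & (h.index <= hi_bp)
    return float(h[mask].sum())


def classify_qc(profile: FragmentProfile, thresholds: QCThresholds | None = None) -> QCVerdict:
    """Assign a usable/unusable verdict to one sample's fragment profile.

    Fails with ``no_material`` when total signal is below the detection
    floor; fails with ``genomic_contamination`` when long (> 2 kb) fragments
    dominate and the cfDNA window itself carries no usable signal. A passing
    sample is ``clean`` or ``tolerable_contamination`` depending on the long
    fraction.
    """
    t = thresholds or QCThresholds()
    window = quantify_window(profile) if not profile.histogram.empty else 0.0
    total = profile.total
    if total < t.min_total_signal:
        return QCVerdict("fail", "no_material", window)
    contaminant_fraction = profile.mass_above(t.long_cutoff_bp) / total
    if contaminant_fraction > t.max_contaminant_fraction and window < t.min_window_signal:
        return QCVerdict("fail", "genomic_contamination", window)
    reason = "clean" if contaminant_fraction <= t.clean_contaminant_fraction else "tolerable_contamination"
    return QCVerdict("pass", reason, window)


def right_size_select(profile: FragmentProfile, cutoff_bp: float = 500) -> FragmentProfile:
    """Remove fragments longer than ``cutoff_bp`` (bead-based right-sided selection)."""
    if cutoff_bp <= 0:
        raise ValueError("cutoff must be positive")
    h = profile.histogram[profile.histogram.index <= cutoff_bp]
    return FragmentProfile(h, profile.sample_id, profile.processing_delay_h, profile.timepoint)


@dataclass
class TTestResult:
    statistic: float
    pvalue: float
    df: float
    significant: bool
    degenerate: bool = False

    alpha: float = field(default=0.05, repr=False)


def compare_yields_unpaired(group_a, group_b, equal_var: bool = True,
                            alpha: float = 0.05) -> TTestResult:
    """Two-sample two-tailed t-test on yields (Student by default, Welch by flag)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("zero variance in both groups: t statistic undefined")
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    df = res.df if hasattr(res, "df") else len(a) + len(b) - 2
    return TTestResult(float(res.statistic), float(res.pvalue), float(df),
                       res.pvalue < alpha, alpha=alpha)


def compare_yields_paired(pre, post, alpha: float = 0.05) -> TTestResult:
    """Paired two-tailed t-test on per-patient yield differences.

    Identical pairs (zero variance of differences) are degenerate: reported
    as p = 1 with a warning rather than an error.
    """
    x = np.asarray(pre, dtype=float)
    y = np.asarray(post, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired groups must have equal length")
    if len(x) < 2:
        raise ValueError("need at least two pairs")
    diff = y - x
    if diff.var(ddof=1) == 0 and np.allclose(diff, diff[0]) and diff[0] == 0:
        warnings.warn("all paired differences are zero; p set to 1")
        return TTestResult(0.0, 1.0, float(len(x) - 1), False, degenerate=True, alpha=alpha)
    if diff.var(ddof=1) == 0:
        # constant nonzero shift: t is infinite, p -> 0
        warnings.warn("paired differences have zero variance; t unbounded")
        return TTestResult(np.inf if diff[0] > 0 else -np.inf, 0.0,
                           float(len(x) - 1), True, degenerate=True, alpha=alpha)
    res = sps.ttest_rel(y, x)
    return TTestResult(float(res.statistic), float(res.pvalue), float(len(x) - 1),
                       res.pvalue < alpha, alpha=alpha)


def read_fragment_profile(path, sample_id: str = "", **meta) -> FragmentProfile:
    """Read a TSV fragment histogram with columns length_bp, abundance."""
    df = pd.read_csv(path, sep="\t")
    h = pd.Series(df["abundance"].values, index=df["length_bp"].values)
    return FragmentProfile(h, sample_id=sample_id, **meta)


def qc_sample_sheet(profiles: dict[str, FragmentProfile],
                    thresholds: QCThresholds | None = None) -> pd.DataFrame:
    """Run classify_qc over a set of samples and tabulate the verdicts."""
    rows = []
    for sid, prof in profiles.items():
        v = classify_qc(prof, thresholds)
        rows.append({"sample_id": sid, "status": v.status, "reason": v.reason,
                     "cfdna_window_yield": v.cfdna_window_yield})
    return pd.DataFrame(rows, columns=["sample_id", "status", "reason", "cfdna_window_yield"])
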