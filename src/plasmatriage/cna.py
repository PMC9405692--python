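"""Copy-number calling from exon-level panel depth ratios.

A deliberately transparent caller: depths are normalized per compartment to
panel mean 1, per-exon log2 ratios of test vs control are thresholded into
gain / neutral / loss states, and adjacent same-state exons of a gene are
merged into one call. Germline events are separated from somatic ones by
running the matched normal against a reference-normal track: a test-side
event that coincides with an identical-state germline event is reported as
germline in origin.

Default thresholds correspond to ~2.5 copies for a gain (log2(2.5/2)) and
~1.5 copies for a loss (log2(1.5/2)) in a diploid background.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

DEPTH_COLS = ("depth_test", "depth_matched", "depth_reference")


@dataclass
class CNAConfig:
    gain_threshold: float = math.log2(1.25)   # >= 2.5 copies
    loss_threshold: float = math.log2(0.75)   # <= 1.5 copies
    cosmic_genes: frozenset = field(default_factory=frozenset)


@dataclass
class CNACall:
    chrom: str
    start: int
    end: int
    gene: str
    n_exons: int
    log2_ratio: float  # mean over merged exons
    copy_estimate: float
    state: str  # gain | loss
    origin: str = "somatic"  # somatic | germline
    cosmic_flag: bool = False


def normalize_depths(coverage: pd.DataFrame,
                     columns: Iterable[str] = DEPTH_COLS) -> pd.DataFrame:
    """Scale each compartment so its panel-wide mean depth is 1."""
    if len(coverage) == 0:
        raise ValueError("coverage table is empty")
    out = coverage.copy()
    for col in columns:
        if col not in out:
            continue
        mean = out[col].mean()
        if mean == 0:
            raise ValueError(f"compartment {col!r} has zero depth everywhere")
        out[col] = out[col] / mean
    return out


def exon_log2_ratio(coverage: pd.DataFrame, test_col: str,
                    control_col: str) -> pd.DataFrame:
    """Per-exon log2(test/control); zero-depth control exons are masked."""
    out = coverage.copy()
    test = out[test_col].to_numpy(dtype=float)
    control = out[control_col].to_numpy(dtype=float)
    masked = control <= 0
    ratio = np.full(len(out), np.nan)
    with np.errstate(divide="ignore"):
        ratio[~masked] = np.log2(test[~masked] / control[~masked])
    out["log2_ratio"] = ratio
    out["masked"] = masked
    out.loc[masked, "mask_reason"] = "zero_control_depth"
    return out


def _exon_state(ratio: float, cfg: CNAConfig) -> str:
    if np.isnan(ratio):
        return "masked"
    if ratio >= cfg.gain_threshold:
        return "gain"
    if ratio <= cfg.loss_threshold:
        return "loss"
    return "neutral"


def call_states(ratios: pd.DataFrame, config: CNAConfig | None = None,
                origin: str = "somatic") -> list[CNACall]:
    """Threshold per-exon ratios and merge adjacent same-state exons per gene."""
    cfg = config or CNAConfig()
    df = ratios.copy()
    df["state"] = [_exon_state(r, cfg) for r in df["log2_ratio"]]
    calls: list[CNACall] = []
    for (chrom, gene), sub in df.groupby(["chrom", "gene"], sort=False):
        sub = sub.sort_values("start")
        run: list = []
        for row in sub.itertuples(index=False):
            if row.state in ("gain", "loss") and run and run[-1].state == row.state:
                run.append(row)
            else:
                if run and run[-1].state in ("gain", "loss"):
                    calls.append(_merge_run(run, chrom, gene, cfg, origin))
                run = [row] if row.state in ("gain", "loss") else []
        if run:
            calls.append(_merge_run(run, chrom, gene, cfg, origin))
    return calls


def _merge_run(run, chrom, gene, cfg: CNAConfig, origin: str) -> CNACall:
    mean_ratio = float(np.mean([r.log2_ratio for r in run]))
    return CNACall(chrom=chrom, start=int(run[0].start), end=int(run[-1].end),
                   gene=gene, n_exons=len(run), log2_ratio=mean_ratio,
                   copy_estimate=2.0 * 2.0 ** mean_ratio, state=run[0].state,
                   origin=origin, cosmic_flag=gene in cfg.cosmic_genes)


def germline_vs_somatic_split(coverage: pd.DataFrame,
                              config: CNAConfig | None = None
                              ) -> tuple[list[CNACall], list[CNACall]]:
    """Separate germline from somatic copy-number calls.

    Germline calls: matched normal vs reference normal. Somatic calls: test
    vs matched normal; any somatic call overlapping an identical-state
    germline call in the same gene is relabeled germline-origin.
    """
    cfg = config or CNAConfig()
    missing = [c for c in DEPTH_COLS if c not in coverage]
    if missing:
        warnings.warn(f"missing coverage tracks {missing}; partial output")
    norm = normalize_depths(coverage, [c for c in DEPTH_COLS if c in coverage])

    germline_calls: list[CNACall] = []
    if {"depth_matched", "depth_reference"} <= set(norm.columns):
        g_ratios = exon_log2_ratio(norm, "depth_matched", "depth_reference")
        germline_calls = call_states(g_ratios, cfg, origin="germline")

    somatic_calls: list[CNACall] = []
    if {"depth_test", "depth_matched"} <= set(norm.columns):
        s_ratios = exon_log2_ratio(norm, "depth_test", "depth_matched")
        somatic_calls = call_states(s_ratios, cfg, origin="somatic")

    germline_index = {(c.chrom, c.gene, c.state) for c in germline_calls}
    for call in somatic_calls:
        if (call.chrom, call.gene, call.state) in germline_index:
            call.origin = "germline"
    return germline_calls, somatic_calls


def calls_to_frame(calls: Iterable[CNACall]) -> pd.DataFrame:
    rows = [vars(c) for c in calls]
    cols = ["chrom", "start", "end", "gene", "n_exons", "log2_ratio",
            "copy_estimate", "state", "origin", "cosmic_flag"]
    return pd.DataFrame(rows, columns=cols)
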