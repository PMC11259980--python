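"""Read-depth copy-number estimation and duplicated region / gene calling.

Raw per-window depth is corrected for local GC content by dividing by the
mean depth of the window's GC bin over a set of diploid control windows
(bin width 0.05), then scaled so control windows average copy number 2.
Duplicated regions are maximal runs of >= 4 consecutive windows with copy
number > 2.5 spanning >= 10 kb; gene copy numbers are medians over fully
encompassed windows (>= 3 required).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .genome import GeneModel

GC_BIN_WIDTH = 0.05


def estimate_copy_number(
    track: pd.DataFrame,
    controls: dict[str, list[tuple[int, int]]],
    min_control_windows: int = 50,
) -> pd.DataFrame:
    """GC-correct a depth track against control regions and scale to CN.

    ``controls`` maps chromosome to intervals believed copy-number 2 (the
    caller must exclude known duplications/deletions).  A window is a
    control window when fully contained in a control interval.  Windows in a
    GC bin with no controls fall back to the global control mean (with a
    warning).  Returns the track with ``corrected`` and ``cn`` columns.
    """
    if not controls:
        raise ValueError("control regions are required")
    df = track.copy()
    in_control = np.zeros(len(df), dtype=bool)
    for i, row in enumerate(df.itertuples()):
        for s, e in controls.get(row.chrom, []):
            if s <= row.start and row.end <= e:
                in_control[i] = True
                break
    if in_control.sum() < min_control_windows:
        raise ValueError(
            f"controls cover only {int(in_control.sum())} windows "
            f"(need >= {min_control_windows})"
        )
    gc_bin = np.minimum((df["gc"] / GC_BIN_WIDTH).astype(int),
                        int(1 / GC_BIN_WIDTH) - 1)
    ctrl = df[in_control]
    ctrl_bins = gc_bin[in_control]
    global_mean = float(ctrl["depth"].mean())
    bin_means = ctrl.groupby(ctrl_bins)["depth"].mean()

    # correction curve: binned control depth means, interpolated at each
    # window's GC; knots sit at each bin's mean control GC (not the bin
    # center) so a linear bias is corrected exactly, with no sawtooth
    gc_knots = ctrl.groupby(ctrl_bins)["gc"].mean().to_numpy()
    denom = np.interp(df["gc"].to_numpy(), gc_knots, bin_means.to_numpy())
    missing_bins = sorted(set(gc_bin) - set(bin_means.index))
    if missing_bins:
        warnings.warn(
            f"GC bins without control windows {missing_bins}; "
            "using the interpolated/edge correction value"
        )
    if len(bin_means) == 0:
        denom = np.full(len(df), global_mean)
    corrected = df["depth"].to_numpy() / denom
    scale = 2.0 / corrected[in_control].mean()
    df["corrected"] = corrected
    df["cn"] = corrected * scale
    return df


def call_duplicated_regions(
    windows: pd.DataFrame,
    cn_min: float = 2.5,
    min_windows: int = 4,
    min_span: int = 10000,
) -> pd.DataFrame:
    """Maximal runs of consecutive windows with CN > ``cn_min``.

    A run is reported when it holds >= ``min_windows`` windows and its
    genomic span (first window start to last window end, masked interior
    included) is >= ``min_span``.  Region CN is the median over member
    windows.  Columns: chrom, start, end, n_windows, median_cn.
    """
    rows = []
    for chrom, grp in windows.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        run: list = []
        for row in grp.itertuples():
            if row.cn > cn_min:
                run.append(row)
            else:
                rows.extend(_emit_run(chrom, run, min_windows, min_span))
                run = []
        rows.extend(_emit_run(chrom, run, min_windows, min_span))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_windows", "median_cn"]
    )


def _emit_run(chrom, run, min_windows, min_span):
    if len(run) < min_windows:
        return []
    start, end = run[0].start, run[-1].end
    if end - start < min_span:
        return []
    return [(chrom, start, end, len(run), float(np.median([w.cn for w in run])))]


def gene_copy_number(
    windows: pd.DataFrame,
    genes: list[GeneModel],
    cn_dup: float = 2.5,
    min_windows: int = 3,
) -> pd.DataFrame:
    """Median copy number over windows fully encompassed by each gene.

    Genes encompassing fewer than ``min_windows`` windows are omitted; a
    gene is flagged duplicated when its median CN exceeds ``cn_dup``.
    Columns: gene_id, n_windows, median_cn, duplicated.
    """
    rows = []
    for g in genes:
        s, e = g.footprint()
        w = windows[
            (windows["chrom"] == g.chrom)
            & (windows["start"] >= s)
            & (windows["end"] <= e)
        ]
        if len(w) < min_windows:
            continue
        med = float(w["cn"].median())
        rows.append((g.gene_id, len(w), med, med > cn_dup))
    return pd.DataFrame(
        rows, columns=["gene_id", "n_windows", "median_cn", "duplicated"]
    )
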