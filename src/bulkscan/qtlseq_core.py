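"""SNP-index statistics, sliding-window profiles, null bands, region calling.

The QTL-seq statistic at a site is the SNP-index of each bulk — the fraction
of reads carrying the non-reference (yellow-parent) allele — and their
difference Δ(SNP-index) = index(high bulk) − index(low bulk).  Loci unlinked
to the trait fluctuate around Δ = 0; loci tightly linked to a causal gene
approach Δ = +1 (with the black parent as reference and the yellow bulk as
"high").

Profiles are smoothed with a sliding window (default 1 Mbp, 10 kbp step);
windows with fewer than 10 SNPs are skipped.  Significance is judged against
a null band obtained by Monte-Carlo simulation of bulk sampling with no QTL:
per window and replicate, each bulk's alt-allele count among the k pooled
lines is Binomial(k, 1/2) (RILs are essentially homozygous) and its reads
are Binomial(window total depth, count/k); the composition draw is shared by
the window's sites because they are almost completely linked at the 1-Mbp
scale.  The 95th and 99th percentiles of the absolute simulated window Δ
form the two-sided band; region calling defaults to positive exceedance of
the 99% cutoff.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd

from bulkscan.variant_filtering import ROLE_BULK_HIGH, ROLE_BULK_LOW, VariantRecord

log = logging.getLogger(__name__)

POINT_COLUMNS = ["chrom", "pos", "index_high", "index_low", "delta", "depth_high", "depth_low"]


def compute_snp_index(records: Iterable[VariantRecord]) -> pd.DataFrame:
    """Per-site SNP-index pair and Δ(SNP-index) from bulk allele depths.

    index = alt reads / (ref reads + alt reads) per bulk;
    delta = index_high − index_low.  Sites where either bulk has zero total
    AD are skipped (logged), as the index is undefined there.
    """
    rows = []
    n_skipped = 0
    for rec in records:
        ad_h = rec.calls[ROLE_BULK_HIGH].ad
        ad_l = rec.calls[ROLE_BULK_LOW].ad
        if ad_h is None or ad_l is None or sum(ad_h) == 0 or sum(ad_l) == 0:
            n_skipped += 1
            continue
        ih = ad_h[1] / (ad_h[0] + ad_h[1])
        il = ad_l[1] / (ad_l[0] + ad_l[1])
        rows.append(
            (rec.chrom, rec.pos, ih, il, ih - il, ad_h[0] + ad_h[1], ad_l[0] + ad_l[1])
        )
    if n_skipped:
        log.info("skipped %d sites with zero allele depth in a bulk", n_skipped)
    df = pd.DataFrame(rows, columns=POINT_COLUMNS)
    return df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def snp_index_from_sim_sites(sites: pd.DataFrame) -> pd.DataFrame:
    """SNP-index table straight from a simulator site table (no VCF round trip).

    Accepts the frame returned by :func:`bulkscan.simbulk.sample_bulk_reads`;
    sites where either bulk has zero total allele depth are dropped, matching
    :func:`compute_snp_index`.
    """
    th = sites["bulk_high_ad_ref"] + sites["bulk_high_ad_alt"]
    tl = sites["bulk_low_ad_ref"] + sites["bulk_low_ad_alt"]
    ok = (th > 0) & (tl > 0)
    ih = sites.loc[ok, "bulk_high_ad_alt"] / th[ok]
    il = sites.loc[ok, "bulk_low_ad_alt"] / tl[ok]
    df = pd.DataFrame(
        {
            "chrom": sites.loc[ok, "chrom"],
            "pos": sites.loc[ok, "pos"],
            "index_high": ih,
            "index_low": il,
            "delta": ih - il,
            "depth_high": th[ok],
            "depth_low": tl[ok],
        }
    )
    return df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def sliding_window_profile(
    points: pd.DataFrame,
    window: int = 1_000_000,
    step: int = 10_000,
    min_snps: int = 10,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Mean Δ(SNP-index) in half-open windows [a, a+W) anchored at 1, 1+s, ...

    Windows containing fewer than ``min_snps`` member sites are not emitted.
    ``chrom_lengths`` bounds the anchor grid; without it the grid runs to the
    last observed site.  Emitted columns include the member-site index range
    [i0, i1) into the (chromosome-sorted) ``points`` frame.
    """
    if window <= 0 or step <= 0 or step > window:
        raise ValueError("need 0 < step <= window")
    out = []
    for chrom, sub in points.groupby("chrom", sort=True):
        sub = sub.sort_values("pos", kind="mergesort")
        pos = sub["pos"].to_numpy()
        delta = sub["delta"].to_numpy()
        idx = sub.index.to_numpy()
        length = (chrom_lengths or {}).get(chrom, int(pos[-1]))
        if length < window:
            starts = np.array([1], dtype=np.int64)
        else:
            starts = np.arange(1, length - window + 2, step, dtype=np.int64)
        ends = np.minimum(starts + window - 1, length)  # inclusive end
        i0 = np.searchsorted(pos, starts, side="left")
        i1 = np.searchsorted(pos, starts + window, side="left")
        n = i1 - i0
        csum = np.concatenate([[0.0], np.cumsum(delta)])
        keep = (n >= min_snps) & (n > 0)
        mean = np.full(starts.size, np.nan)
        mean[keep] = (csum[i1[keep]] - csum[i0[keep]]) / n[keep]
        for j in np.flatnonzero(keep):
            out.append(
                (
                    chrom,
                    int(starts[j]),
                    int(ends[j]),
                    int(n[j]),
                    float(mean[j]),
                    int(idx[i0[j]]),
                    int(idx[i1[j] - 1]) + 1,
                )
            )
    return pd.DataFrame(
        out, columns=["chrom", "start", "end", "n_snps", "mean_delta", "i0", "i1"]
    )


def _nearest_rank_quantile(matrix: np.ndarray, q: float) -> np.ndarray:
    """Nearest-rank (inverted-CDF) empirical quantile along the replicate axis."""
    return np.quantile(matrix, q, axis=1, method="inverted_cdf")


#: above this total depth the binomial read draw switches to its normal limit
_NORMAL_APPROX_DEPTH = 200


def _null_index(
    rng: np.random.Generator, depth: np.ndarray, p: np.ndarray
) -> np.ndarray:
    """Null SNP-index draws: Binomial(depth, p)/depth per row of depths.

    ``p`` holds one pooled allele fraction per replicate (shared across
    rows); rows with depth above ``_NORMAL_APPROX_DEPTH`` use the normal
    limit N(p, p(1-p)/depth) clipped to [0, 1] — at window total depths of
    hundreds to thousands of reads the approximation error is far below the
    Monte-Carlo noise — while small depths (single-SNP windows, shallow
    data) keep the exact binomial.
    """
    out = np.empty((depth.size, p.size), dtype=np.float64)
    small = depth <= _NORMAL_APPROX_DEPTH
    if np.any(small):
        d = depth[small, None]
        out[small] = rng.binomial(d, np.broadcast_to(p, (int(small.sum()), p.size))) / d
    if np.any(~small):
        big = ~small
        d = depth[big, None]
        sd = np.sqrt(p * (1.0 - p) / d)
        out[big] = np.clip(p + rng.standard_normal((int(big.sum()), p.size)) * sd, 0.0, 1.0)
    return out


def simulate_null_band(
    windows: pd.DataFrame,
    points: pd.DataFrame,
    bulk_size: int = 25,
    n_replicates: int = 100_000,
    levels: tuple[float, ...] = (0.95, 0.99),
    seed: int | np.random.Generator | None = None,
    replicate_chunk: int = 20_000,
    cache: dict | None = None,
) -> pd.DataFrame:
    """Null |mean Δ| cutoffs per window under the no-QTL two-stage binomial model.

    Per window and replicate: each bulk's alt-allele count among the k pooled
    (essentially homozygous) lines is Binomial(k, 1/2), and the bulk's reads
    are Binomial(total member depth, count / k); Δ is the difference of the
    two simulated indices and the cutoffs are nearest-rank percentiles of
    |Δ| over replicates.

    The pooled-line composition is drawn once per window — not per site —
    because every site in a window descends from the same sampled bulk lines
    and within-window recombination is negligible at the 1-Mbp scale of a
    RIL genome (complete-linkage null).  For a single-SNP window this is
    exactly the per-site two-stage binomial.  Windows with identical total
    depths share cutoffs through ``cache`` (pass a dict to reuse draws
    across repeated profiles).

    Returns ``windows`` with one ``cutoff_<level>`` column per level.
    """
    if bulk_size <= 0:
        raise ValueError("bulk_size must be positive")
    if n_replicates <= 0:
        raise ValueError("n_replicates must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    windows = windows.copy()
    colnames = [f"cutoff_{int(round(level * 100))}" for level in levels]
    for c in colnames:
        windows[c] = np.nan
    if cache is None:
        cache = {}

    dh_all = points["depth_high"].to_numpy(dtype=np.int64)
    dl_all = points["depth_low"].to_numpy(dtype=np.int64)
    if np.any(dh_all <= 0) or np.any(dl_all <= 0):
        raise ValueError("null band requires positive depths at every member site")
    csum_h = np.concatenate([[0], np.cumsum(dh_all)])
    csum_l = np.concatenate([[0], np.cumsum(dl_all)])

    i0 = windows["i0"].to_numpy(dtype=np.int64)
    i1 = windows["i1"].to_numpy(dtype=np.int64)
    if np.any(i1 <= i0):
        raise ValueError("every window needs at least one member site with depth info")
    tot_h = csum_h[i1] - csum_h[i0]
    tot_l = csum_l[i1] - csum_l[i0]
    keys = list(zip(tot_h.tolist(), tot_l.tolist()))
    todo = sorted({k for k in keys if k not in cache})
    if todo:
        dh = np.array([k[0] for k in todo], dtype=np.int64)
        dl = np.array([k[1] for k in todo], dtype=np.int64)
        abs_delta = np.empty((len(todo), n_replicates), dtype=np.float32)
        done = 0
        while done < n_replicates:
            r = min(replicate_chunk, n_replicates - done)
            # one pooled-composition replicate stream, shared across windows
            ph = rng.binomial(bulk_size, 0.5, size=r) / bulk_size
            pl = rng.binomial(bulk_size, 0.5, size=r) / bulk_size
            ih = _null_index(rng, dh, ph)
            il = _null_index(rng, dl, pl)
            abs_delta[:, done : done + r] = np.abs(ih - il)
            done += r
        for t, key in enumerate(todo):
            cache[key] = [
                float(np.quantile(abs_delta[t], lvl, method="inverted_cdf"))
                for lvl in levels
            ]
    cuts = np.array([cache[k] for k in keys])
    for j, c in enumerate(colnames):
        windows[c] = cuts[:, j]
    return windows


def call_candidate_regions(
    windows: pd.DataFrame, level: float = 0.99, two_sided: bool = False
) -> pd.DataFrame:
    """Merge maximal runs of consecutive significant windows into regions.

    A window is significant when its mean Δ exceeds the cutoff at ``level``
    (positive exceedance by default; ``two_sided=True`` uses |mean Δ|).
    Runs are broken only by an emitted non-significant window — windows
    skipped for having too few SNPs do not interrupt a run.  Each region
    reports the member window with the largest (signed or absolute) mean Δ
    as its peak, along with peak_difference = peak Δ − peak-window cutoff.
    """
    col = f"cutoff_{int(round(level * 100))}"
    if col not in windows.columns:
        raise ValueError(f"no {col} column: band not computed at level {level}")
    stat = windows["mean_delta"].abs() if two_sided else windows["mean_delta"]
    sig = stat > windows[col]
    regions = []
    for chrom, wsub in windows.groupby("chrom", sort=True):
        wsub = wsub.sort_values("start", kind="mergesort")
        run: list[int] = []
        for widx in wsub.index:
            if sig.loc[widx]:
                run.append(widx)
            elif run:
                regions.append(_close_region(windows, run, col, two_sided))
                run = []
        if run:
            regions.append(_close_region(windows, run, col, two_sided))
    return pd.DataFrame(
        regions,
        columns=[
            "chrom",
            "start",
            "end",
            "peak_delta",
            "peak_threshold",
            "peak_difference",
            "peak_window_start",
            "peak_window_end",
            "n_windows",
        ],
    )


def _close_region(windows: pd.DataFrame, run: list[int], col: str, two_sided: bool) -> dict:
    sub = windows.loc[run]
    stat = sub["mean_delta"].abs() if two_sided else sub["mean_delta"]
    peak_idx = stat.idxmax()
    peak = windows.loc[peak_idx]
    return {
        "chrom": peak["chrom"],
        "start": int(sub["start"].min()),
        "end": int(sub["end"].max()),
        "peak_delta": float(peak["mean_delta"]),
        "peak_threshold": float(peak[col]),
        "peak_difference": float(
            (abs(peak["mean_delta"]) if two_sided else peak["mean_delta"]) - peak[col]
        ),
        "peak_window_start": int(peak["start"]),
        "peak_window_end": int(peak["end"]),
        "n_windows": int(len(run)),
    }


def merge_overlapping_regions(regions: pd.DataFrame) -> pd.DataFrame:
    """Union physically overlapping candidate regions per chromosome.

    Two significant runs separated by a single sub-threshold window still
    overlap in base pairs, because windows are much wider than the step;
    such calls describe one candidate interval.  Peak statistics come from
    the merged member with the larger peak Δ.
    """
    if len(regions) == 0:
        return regions
    out = []
    for _, sub in regions.groupby("chrom", sort=True):
        sub = sub.sort_values("start", kind="mergesort")
        cur = sub.iloc[0].to_dict()
        for _, row in sub.iloc[1:].iterrows():
            if row["start"] <= cur["end"]:
                cur["end"] = max(cur["end"], row["end"])
                cur["n_windows"] += row["n_windows"]
                if row["peak_delta"] > cur["peak_delta"]:
                    for key in (
                        "peak_delta",
                        "peak_threshold",
                        "peak_difference",
                        "peak_window_start",
                        "peak_window_end",
                    ):
                        cur[key] = row[key]
            else:
                out.append(cur)
                cur = row.to_dict()
        out.append(cur)
    return pd.DataFrame(out, columns=regions.columns).reset_index(drop=True)


def summarize_regions(
    regions: pd.DataFrame, unit: str = "bp"
) -> tuple[float, pd.Series]:
    """Overall and per-chromosome candidate-interval spans, in Mbp (2 dp).

    ``regions`` needs ``chrom``, ``start`` and ``end`` columns; ``unit`` says
    whether those coordinates are in ``"bp"`` or already in ``"mbp"``.
    Regions must be non-overlapping within a chromosome.
    """
    if unit not in ("bp", "mbp"):
        raise ValueError("unit must be 'bp' or 'mbp'")
    scale = 1e-6 if unit == "bp" else 1.0
    if len(regions) == 0:
        return 0.0, pd.Series(dtype=float)
    for chrom, sub in regions.groupby("chrom"):
        sub = sub.sort_values("start")
        if (sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]).any():
            raise ValueError(f"overlapping regions on {chrom}; merge before summarizing")
    width = (regions["end"] - regions["start"]) * scale
    per_chrom = (
        width.groupby(regions["chrom"]).sum().round(2).sort_values(ascending=False)
    )
    total = round(float(width.sum()), 2)
    return total, per_chrom
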