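"""P-site offset calibration and A-site localization for footprint reads.

Ribosome-protected fragments (RPFs, ~28-31 nt) shield the P- and A-site
codons of the translating ribosome.  The distance from a read's 5' end to the
first base of the P-site codon (the P-site offset) is calibrated per read
length from the pile-up of 5' ends upstream of start codons: initiating
ribosomes place their P-site on the AUG, so the 5'-end metagene peaks at
``cds_start - offset``.  The A-site tri-nucleotide is the codon immediately
downstream of the P-site; only A-site overlap is used when counting footprint
support for an allele.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .io import BASES

OFFSET_COLUMNS = (
    "length",
    "offset",
    "n_reads",
    "peak_height",
    "median_bin",
    "frame0",
    "frame1",
    "frame2",
    "qc_pass",
)


def frame_fractions(reads: pd.DataFrame, cds_models: pd.DataFrame) -> pd.DataFrame:
    """Per-length fractions of reads whose 5' end falls on each codon frame.

    Frame 0 means the 5' end sits on the first base of a codon, i.e.
    ``(pos5 - cds_start) mod 3 == 0``; only reads overlapping the CDS count.
    """
    merged = reads.merge(cds_models, on="gene", how="inner")
    ov = merged[
        (merged["pos5"] + merged["length"] > merged["cds_start"])
        & (merged["pos5"] < merged["cds_end"])
    ]
    if ov.empty:
        raise ValueError("no CDS-overlapping reads; cannot compute frame fractions")
    frame = (ov["pos5"] - ov["cds_start"]).mod(3)
    tab = (
        pd.crosstab(ov["length"], frame, normalize="index")
        .reindex(columns=[0, 1, 2], fill_value=0.0)
        .rename(columns={0: "frame0", 1: "frame1", 2: "frame2"})
    )
    return tab.reset_index()


class PsiteOffsetModel(BaseEstimator):
    """Per-read-length P-site offset calibration from the start-codon metagene.

    sklearn-style estimator: :meth:`fit` learns one offset per read length
    from the argmax of the 5'-end histogram relative to the start codon
    (window ``window``, ties broken toward the smaller offset); lengths with
    fewer than ``min_reads`` in-window reads, or whose peak is lower than
    ``min_peak_ratio`` times the median window bin, are QC-flagged and
    excluded.  :meth:`transform` maps reads to their A-site intervals.

    Attributes
    ----------
    offsets_ : dict[int, int]
        Read length -> P-site offset for QC-passing lengths.
    table_ : pandas.DataFrame
        Full diagnostic table (offset, read counts, peak height, frame
        fractions, QC flag) for every observed length.
    n_skipped_ : int
        Reads dropped by the last :meth:`transform` because their length was
        unknown or QC-flagged.

    A length is QC-flagged when it has fewer than ``min_reads`` in-window
    reads, when its peak is below ``min_peak_ratio`` x the median window bin,
    or when its dominant-frame fraction falls below ``min_frame_conc``
    (poorly phased libraries give unreliable argmax offsets; which frame
    dominates depends on the offset modulo 3, so the maximum over the three
    frame fractions is used).
    """

    def __init__(
        self,
        window: tuple[int, int] = (-40, 10),
        min_reads: int = 200,
        min_peak_ratio: float = 2.0,
        min_frame_conc: float = 0.6,
        length_range: tuple[int, int] = (25, 35),
    ):
        self.window = window
        self.min_reads = min_reads
        self.min_peak_ratio = min_peak_ratio
        self.min_frame_conc = min_frame_conc
        self.length_range = length_range

    def fit(self, reads: pd.DataFrame, cds_models: pd.DataFrame) -> "PsiteOffsetModel":
        lo, hi = self.window
        reads = reads[
            (reads["length"] >= self.length_range[0])
            & (reads["length"] <= self.length_range[1])
        ]
        merged = reads.merge(
            cds_models[["gene", "cds_start", "cds_end"]], on="gene", how="inner"
        )
        merged = merged.assign(rel=merged["pos5"] - merged["cds_start"])
        frames = frame_fractions(reads, cds_models).set_index("length")

        rows = []
        offsets: dict[int, int] = {}
        for length, sub in merged.groupby("length", sort=True):
            inwin = sub[(sub["rel"] >= lo) & (sub["rel"] <= hi)]
            n = len(inwin)
            grid = np.arange(lo, hi + 1)
            hist = (
                inwin["rel"].value_counts().reindex(grid, fill_value=0).to_numpy()
            )
            median_bin = float(np.median(hist))
            # candidate peaks must yield a valid offset: 0 <= offset < length
            cand = (grid <= 0) & (grid > -length)
            if n == 0 or not cand.any():
                rows.append(self._row(length, -1, n, 0.0, median_bin, frames, False))
                continue
            heights = np.where(cand, hist, -1)
            peak_height = heights.max()
            # ties broken toward the smaller offset (the larger rel position)
            peak_rel = grid[heights == peak_height].max()
            offset = int(-peak_rel)
            frame_conc = (
                float(frames.loc[length, ["frame0", "frame1", "frame2"]].max())
                if length in frames.index
                else 0.0
            )
            qc = (
                (n >= self.min_reads)
                and (peak_height >= self.min_peak_ratio * median_bin)
                and peak_height > 0
                and frame_conc >= self.min_frame_conc
            )
            rows.append(
                self._row(length, offset, n, float(peak_height), median_bin, frames, qc)
            )
            if qc:
                offsets[int(length)] = offset
        self.table_ = pd.DataFrame(rows, columns=list(OFFSET_COLUMNS))
        self.offsets_ = offsets
        self.n_skipped_ = 0
        if not offsets:
            raise ValueError(
                "P-site calibration failed: every read length was QC-flagged"
            )
        return self

    @staticmethod
    def _row(length, offset, n, peak, median_bin, frames, qc):
        f = frames.loc[length] if length in frames.index else None
        return {
            "length": int(length),
            "offset": int(offset),
            "n_reads": int(n),
            "peak_height": peak,
            "median_bin": median_bin,
            "frame0": float(f["frame0"]) if f is not None else np.nan,
            "frame1": float(f["frame1"]) if f is not None else np.nan,
            "frame2": float(f["frame2"]) if f is not None else np.nan,
            "qc_pass": bool(qc),
        }

    def transform(self, reads: pd.DataFrame) -> pd.DataFrame:
        """Attach ``asite_start``/``asite_end`` columns; drop reads whose
        length has no QC-passing offset (counted in ``n_skipped_``)."""
        off = reads["length"].map(self.offsets_)
        keep = off.notna()
        self.n_skipped_ = int((~keep).sum())
        out = reads[keep].copy()
        out["asite_start"] = (out["pos5"] + off[keep] + 3).astype(int)
        out["asite_end"] = out["asite_start"] + 3
        return out


def infer_psite_offsets(
    reads: pd.DataFrame,
    cds_models: pd.DataFrame,
    window: tuple[int, int] = (-40, 10),
    min_reads: int = 200,
    min_peak_ratio: float = 2.0,
) -> pd.DataFrame:
    """Functional wrapper around :class:`PsiteOffsetModel`; returns ``table_``."""
    model = PsiteOffsetModel(
        window=window, min_reads=min_reads, min_peak_ratio=min_peak_ratio
    )
    model.fit(reads, cds_models)
    return model.table_


def asite_interval(pos5: int, offset: int) -> tuple[int, int]:
    """A-site tri-nucleotide interval of a read: the codon just downstream of
    the P-site, ``[pos5 + offset + 3, pos5 + offset + 6)``."""
    return pos5 + offset + 3, pos5 + offset + 6


def asite_site_counts(
    reads: pd.DataFrame,
    offsets: dict[int, int],
    sites: pd.DataFrame,
) -> pd.DataFrame:
    """Per-site allele counts over reads whose A-site covers the site.

    ``reads`` carry an ``allele`` column with the base each read shows at the
    site it covers (synthetic/fixture reads are labelled; real data arrives
    as pre-tabulated count tables instead).  Reads with unlabelled alleles or
    uncalibrated lengths are ignored.  Returns one row per (gene, pos,
    sample) with columns ``A,C,G,T``.
    """
    r = reads[reads["allele"].isin(BASES)].copy()
    off = r["length"].map(offsets)
    r = r[off.notna()]
    r["asite_start"] = (r["pos5"] + off[off.notna()] + 3).astype(int)

    out_rows = []
    site_keys = sites[["gene", "pos"]].drop_duplicates()
    for _, s in site_keys.iterrows():
        hit = r[
            (r["gene"] == s["gene"])
            & (r["asite_start"] <= s["pos"])
            & (s["pos"] < r["asite_start"] + 3)
        ]
        for sample, sub in hit.groupby("sample"):
            counts = sub["allele"].value_counts()
            out_rows.append(
                {
                    "gene": s["gene"],
                    "pos": int(s["pos"]),
                    "sample": sample,
                    **{b: int(counts.get(b, 0)) for b in BASES},
                }
            )
    return pd.DataFrame(out_rows, columns=["gene", "pos", "sample", *BASES])
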