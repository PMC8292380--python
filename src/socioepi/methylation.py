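"""Per-CpG methylated/total read-count container and its text formats.

Coordinates are 0-based half-open internally.  Bismark coverage files
(chrom, start, end, percent, count_methylated, count_unmethylated) are
1-based inclusive and are converted on read/write.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["MethylationCounts"]


class MethylationCounts:
    """Methylated and total read counts at CpG sites across individuals.

    Parameters
    ----------
    sites : DataFrame with columns ``chrom, start, end`` (0-based half-open).
    individuals : ordered individual ids, one per count column.
    meth, total : (n_sites, n_individuals) integer arrays with
        0 <= meth <= total elementwise.
    """

    def __init__(self, sites: pd.DataFrame, individuals: list[str],
                 meth: np.ndarray, total: np.ndarray):
        sites = sites.reset_index(drop=True)
        meth = np.asarray(meth)
        total = np.asarray(total)
        if meth.shape != total.shape or meth.shape != (len(sites), len(individuals)):
            raise ValueError("meth/total shapes must be (n_sites, n_individuals)")
        if np.any(meth < 0) or np.any(meth > total):
            raise ValueError("require 0 <= methylated <= total at every cell")
        self.sites = sites
        self.individuals = list(individuals)
        self.meth = meth
        self.total = total

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def site_ids(self) -> pd.Series:
        return self.sites["chrom"].astype(str) + ":" + self.sites["start"].astype(str)

    def fractions(self) -> np.ndarray:
        """Methylated fraction per cell; NaN where total == 0."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.total > 0, self.meth / np.maximum(self.total, 1), np.nan)

    def subset_sites(self, mask) -> "MethylationCounts":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return MethylationCounts(self.sites.iloc[idx], self.individuals,
                                 self.meth[idx], self.total[idx])

    def reorder_individuals(self, order: list[str]) -> "MethylationCounts":
        pos = [self.individuals.index(i) for i in order]
        return MethylationCounts(self.sites, order, self.meth[:, pos], self.total[:, pos])

    # ------------------------------------------------------------------ I/O

    def to_bismark_dir(self, directory: str | Path) -> None:
        """One Bismark-coverage-style TSV per individual (1-based inclusive)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        frac = self.fractions()
        for j, ind in enumerate(self.individuals):
            df = pd.DataFrame({
                "chrom": self.sites["chrom"],
                "start": self.sites["start"] + 1,
                "end": self.sites["end"],
                "percent": np.round(100.0 * np.nan_to_num(frac[:, j]), 6),
                "count_methylated": self.meth[:, j],
                "count_unmethylated": self.total[:, j] - self.meth[:, j],
            })
            df.to_csv(directory / f"{ind}.cov.tsv", sep="\t", header=False, index=False)

    @classmethod
    def from_bismark_dir(cls, directory: str | Path) -> "MethylationCounts":
        directory = Path(directory)
        paths = sorted(directory.glob("*.cov.tsv"))
        if not paths:
            raise FileNotFoundError(f"no *.cov.tsv files under {directory}")
        names = ["chrom", "start", "end", "percent", "count_methylated", "count_unmethylated"]
        per_ind = {}
        for path in paths:
            ind = path.name[: -len(".cov.tsv")]
            df = pd.read_csv(path, sep="\t", header=None, names=names)
            df["start"] -= 1  # to 0-based half-open
            per_ind[ind] = df
        individuals = list(per_ind)
        key = ["chrom", "start", "end"]
        sites = per_ind[individuals[0]][key]
        meth = np.zeros((len(sites), len(individuals)), dtype=np.int64)
        total = np.zeros_like(meth)
        for j, ind in enumerate(individuals):
            df = per_ind[ind]
            if not df[key].equals(sites):
                raise ValueError(f"site list for {ind} does not match the first individual")
            meth[:, j] = df["count_methylated"].to_numpy()
            total[:, j] = (df["count_methylated"] + df["count_unmethylated"]).to_numpy()
        return cls(sites, individuals, meth, total)

    def to_wide(self, path: str | Path) -> None:
        """Wide matrix variant: one row per site, meth/total columns per animal."""
        out = self.sites.copy()
        for j, ind in enumerate(self.individuals):
            out[f"{ind}.meth"] = self.meth[:, j]
            out[f"{ind}.total"] = self.total[:, j]
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_wide(cls, path: str | Path) -> "MethylationCounts":
        df = pd.read_csv(path, sep="\t")
        meth_cols = [c for c in df.columns if c.endswith(".meth")]
        individuals = [c[: -len(".meth")] for c in meth_cols]
        meth = df[[f"{i}.meth" for i in individuals]].to_numpy(dtype=np.int64)
        total = df[[f"{i}.total" for i in individuals]].to_numpy(dtype=np.int64)
        return cls(df[["chrom", "start", "end"]], individuals, meth, total)
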