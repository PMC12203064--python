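"""Reading, writing and normalizing community (ASV) count tables.

The central observed object is a :class:`CommunityMatrix`: integer read
counts of taxa (rows) by samples (columns), carrying per-sample sampling
times (days since the first sample of each station) and station labels.
Presence-absence dynamics are analyzed on the binarized matrix; counts are
normalized across samples by repeated rarefaction (subsampling without
replacement to a common depth).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "CommunityMatrix",
    "PresenceMatrix",
    "EnvironmentSeries",
    "read_asv_table",
    "write_asv_table",
    "read_metadata",
    "write_metadata",
    "binarize",
    "rarefy",
    "repeat_rarefy",
]

ENV_COLUMNS = ("salinity", "temperature", "pH", "NOx", "PO4")


def _check_unique(ids, what: str) -> None:
    seen = set()
    dupes = sorted({i for i in ids if i in seen or seen.add(i)})
    if dupes:
        raise ValueError(f"duplicate {what}: {dupes[:5]}")


@dataclass
class CommunityMatrix:
    """Integer count table (taxa x samples) with sampling metadata.

    Parameters
    ----------
    counts
        Non-negative integer array, shape ``(n_taxa, n_samples)``.
    taxon_ids, sample_ids
        Unique string identifiers for the rows / columns.
    times
        Days since the first sample, per sample; strictly increasing
        within each station.
    station
        Station label per sample.
    """

    counts: np.ndarray
    taxon_ids: list[str]
    sample_ids: list[str]
    times: np.ndarray = field(default=None)  # type: ignore[assignment]
    station: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (taxa x samples)")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if np.any(self.counts != np.floor(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        n_taxa, n_samples = self.counts.shape
        if len(self.taxon_ids) != n_taxa:
            raise ValueError("taxon_ids length does not match counts")
        if len(self.sample_ids) != n_samples:
            raise ValueError("sample_ids length does not match counts")
        _check_unique(self.taxon_ids, "taxon_ids")
        _check_unique(self.sample_ids, "sample_ids")
        if self.times is None:
            self.times = np.arange(n_samples, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.times.shape != (n_samples,):
            raise ValueError("times length does not match number of samples")
        if np.any(self.times < 0):
            raise ValueError("times must be non-negative")
        if self.station is None:
            self.station = np.array(["S01"] * n_samples)
        self.station = np.asarray(self.station, dtype=object)
        if self.station.shape != (n_samples,):
            raise ValueError("station length does not match number of samples")
        for st in self.stations:
            t = self.times[self.station == st]
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"times not strictly increasing within station {st!r}")

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def stations(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.station:
            seen.setdefault(str(s), None)
        return list(seen)

    def sample_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def subset_station(self, station: str) -> "CommunityMatrix":
        """Return the columns belonging to one station, in time order."""
        mask = self.station == station
        if not mask.any():
            raise KeyError(f"unknown station {station!r}")
        idx = np.flatnonzero(mask)
        return replace(
            self,
            counts=self.counts[:, idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            times=self.times[idx],
            station=self.station[idx],
        )

    def relative_abundance(self) -> np.ndarray:
        """Column-normalized counts (each sample sums to 1)."""
        totals = self.sample_sums().astype(float)
        if np.any(totals == 0):
            raise ValueError("cannot normalize sample(s) with zero total count")
        return self.counts / totals


@dataclass
class PresenceMatrix:
    """Binary occupancy table (taxa x samples) sharing CommunityMatrix axes."""

    presence: np.ndarray
    taxon_ids: list[str]
    sample_ids: list[str]
    times: np.ndarray
    station: np.ndarray

    def __post_init__(self):
        self.presence = np.asarray(self.presence)
        if not np.isin(self.presence, (0, 1)).all():
            raise ValueError("presence entries must be 0 or 1")
        self.presence = self.presence.astype(np.int8)
        self.times = np.asarray(self.times, dtype=float)
        self.station = np.asarray(self.station, dtype=object)

    @property
    def n_taxa(self) -> int:
        return self.presence.shape[0]

    @property
    def n_samples(self) -> int:
        return self.presence.shape[1]

    @property
    def stations(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.station:
            seen.setdefault(str(s), None)
        return list(seen)

    def subset_station(self, station: str) -> "PresenceMatrix":
        mask = self.station == station
        if not mask.any():
            raise KeyError(f"unknown station {station!r}")
        idx = np.flatnonzero(mask)
        return PresenceMatrix(
            presence=self.presence[:, idx],
            taxon_ids=self.taxon_ids,
            sample_ids=[self.sample_ids[i] for i in idx],
            times=self.times[idx],
            station=self.station[idx],
        )


@dataclass
class EnvironmentSeries:
    """Per-sample environmental covariates aligned to a CommunityMatrix.

    Salinity (PSU) is the primary covariate; temperature (degC), pH, NOx
    and PO4 (umol/L) ride along.
    """

    sample_ids: list[str]
    salinity: np.ndarray
    temperature: np.ndarray = None  # type: ignore[assignment]
    pH: np.ndarray = None  # type: ignore[assignment]
    NOx: np.ndarray = None  # type: ignore[assignment]
    PO4: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        self.sample_ids = [str(s) for s in self.sample_ids]
        _check_unique(self.sample_ids, "sample_ids")
        n = len(self.sample_ids)
        self.salinity = np.asarray(self.salinity, dtype=float)
        if self.salinity.shape != (n,):
            raise ValueError("salinity length does not match sample_ids")
        if np.any(self.salinity < 0):
            raise ValueError("salinity must be >= 0")
        for name in ("temperature", "pH", "NOx", "PO4"):
            v = getattr(self, name)
            if v is None:
                v = np.full(n, np.nan)
            v = np.asarray(v, dtype=float)
            if v.shape != (n,):
                raise ValueError(f"{name} length does not match sample_ids")
            setattr(self, name, v)

    def covariate(self, name: str = "salinity") -> np.ndarray:
        if name not in ENV_COLUMNS:
            raise KeyError(f"unknown covariate {name!r}; choose from {ENV_COLUMNS}")
        return getattr(self, name)

    def align(self, sample_ids: list[str]) -> "EnvironmentSeries":
        """Reorder/subset rows to match the given sample_ids."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise KeyError(f"samples missing from environment series: {missing[:5]}")
        idx = [pos[s] for s in sample_ids]
        return EnvironmentSeries(
            sample_ids=list(sample_ids),
            salinity=self.salinity[idx],
            temperature=self.temperature[idx],
            pH=self.pH[idx],
            NOx=self.NOx[idx],
            PO4=self.PO4[idx],
        )


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def read_asv_table(path, metadata=None) -> CommunityMatrix:
    """Read a taxa-by-samples ASV count table from TSV.

    The file must have a header whose first field is literally
    ``taxon_id`` followed by the sample identifiers; all cells are
    non-negative integers.  If ``metadata`` (a path or the DataFrame from
    :func:`read_metadata`) is given, sampling times and station labels are
    taken from it and the columns are ordered by (station, time);
    otherwise samples keep file order with times 0,1,2,...
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if not header or header[0] != "taxon_id":
        raise ValueError("first column header must be 'taxon_id'")
    sample_ids = header[1:]
    _check_unique(sample_ids, "sample column names")
    df = pd.read_csv(path, sep="\t", header=0, dtype=str, skiprows=0)
    taxon_ids = df.iloc[:, 0].tolist()
    raw = df.iloc[:, 1:].to_numpy()
    try:
        counts = raw.astype(np.int64)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-integer cell in ASV table: {exc}") from None
    times = station = None
    if metadata is not None:
        meta = metadata if isinstance(metadata, pd.DataFrame) else read_metadata(metadata)[0]
        meta = meta.set_index("sample_id").loc[sample_ids]
        order = np.lexsort((meta["time"].to_numpy(), meta["station"].to_numpy()))
        sample_ids = [sample_ids[i] for i in order]
        counts = counts[:, order]
        times = meta["time"].to_numpy(dtype=float)[order]
        station = meta["station"].to_numpy()[order]
    return CommunityMatrix(counts, taxon_ids, sample_ids, times, station)


def write_asv_table(cm: CommunityMatrix, path) -> None:
    df = pd.DataFrame(cm.counts, columns=cm.sample_ids)
    df.insert(0, "taxon_id", cm.taxon_ids)
    df.to_csv(path, sep="\t", index=False)


def read_metadata(path):
    """Read sample metadata TSV; return ``(meta_df, EnvironmentSeries)``.

    Expected columns: ``sample_id, station, date, salinity, temperature,
    pH, NOx, PO4`` with ISO-8601 dates.  A ``time`` column (days since the
    earliest date of each station) is added to the returned frame.
    """
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "station": str})
    required = {"sample_id", "station", "date", "salinity"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    _check_unique(meta["sample_id"], "sample_id")
    dates = pd.to_datetime(meta["date"], format="%Y-%m-%d")
    t0 = dates.groupby(meta["station"]).transform("min")
    meta = meta.copy()
    meta["time"] = (dates - t0).dt.days.astype(float)
    env = EnvironmentSeries(
        sample_ids=meta["sample_id"].tolist(),
        salinity=meta["salinity"].to_numpy(dtype=float),
        temperature=meta.get("temperature"),
        pH=meta.get("pH"),
        NOx=meta.get("NOx"),
        PO4=meta.get("PO4"),
    )
    return meta, env


def write_metadata(meta: pd.DataFrame, path) -> None:
    cols = ["sample_id", "station", "date", "salinity", "temperature", "pH", "NOx", "PO4"]
    meta.loc[:, [c for c in cols if c in meta.columns]].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Binarize and rarefy
# ---------------------------------------------------------------------------

def binarize(cm: CommunityMatrix) -> PresenceMatrix:
    """Presence-absence view: 1 wherever the count is positive."""
    return PresenceMatrix(
        presence=(cm.counts > 0).astype(np.int8),
        taxon_ids=cm.taxon_ids,
        sample_ids=cm.sample_ids,
        times=cm.times,
        station=cm.station,
    )


def rarefy(cm: CommunityMatrix, depth: int, seed: int) -> CommunityMatrix:
    """Subsample every sample to ``depth`` reads without replacement.

    Each column is drawn from a multivariate hypergeometric distribution
    over that sample's read pool, so column sums equal ``depth`` exactly
    and no count increases.  Taxa rows are retained even if they end up
    all-zero, keeping axes stable across repetitions.
    """
    depth = int(depth)
    if depth <= 0:
        raise ValueError("depth must be a positive integer")
    totals = cm.sample_sums()
    shallow = [s for s, t in zip(cm.sample_ids, totals) if t < depth]
    if shallow:
        raise ValueError(
            f"samples shallower than depth {depth}: {shallow}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(cm.counts)
    for j in range(cm.n_samples):
        col = cm.counts[:, j]
        if totals[j] == depth:
            out[:, j] = col
        else:
            out[:, j] = rng.multivariate_hypergeometric(col, depth)
    return replace(cm, counts=out)


def repeat_rarefy(cm: CommunityMatrix, depth: int, n_rep: int = 100, seed: int = 0):
    """``n_rep`` independent rarefactions with per-repetition seeds ``seed + i``.

    Downstream statistics are computed per repetition and averaged by the
    caller.
    """
    n_rep = int(n_rep)
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    return [rarefy(cm, depth, seed + i) for i in range(n_rep)]
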