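"""Correlated Poisson spike-train generation on a discrete time grid.

Presynaptic activity is modelled as Bernoulli processes on bins of width
``dt``: each neuron fires in a bin with probability ``q = rate * dt`` and
"instantaneous" pairwise correlations are correlations between same-bin
spike counts.  Populations are organised into groups with a uniform
correlation coefficient inside each group and a per-group-pair coefficient
across groups.

The generator uses a latent-source mixture: every group owns a latent
Bernoulli train, every correlated group pair owns another, and in each bin
a neuron copies its group latent with probability ``a_g``, the pair latent
with probability ``sqrt(c_gh)``, or draws a fresh Bernoulli variable.
Because the branches are mutually exclusive within a bin, the marginal of
every neuron is exactly Bernoulli(q) and the correlation between two
neurons equals the summed product of their shared copy probabilities --
``a_g**2 + sum_h c_gh`` within a group (solved so it equals the requested
coefficient) and ``c_gh`` across groups, exactly, at any q.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

__all__ = [
    "CorrelationSpec",
    "SpikeTrainSet",
    "EmpiricalStats",
    "AdmissibilityError",
    "build_correlation_matrix",
    "generate_trains",
    "iter_event_chunks",
    "empirical_statistics",
]

#: internal generation chunk, in ms.  Fixed so that results do not depend on
#: how a caller slices a simulation into pieces.
CHUNK_MS = 5000.0

# stream-kind identifiers entering the SeedSequence entropy tuple
_KIND_GROUP = 1
_KIND_PAIR = 2
_KIND_CHILD = 3

#: sentinel reported for correlations that are undefined (silent neuron)
UNDEFINED_CORR = -2.0


class AdmissibilityError(ValueError):
    """Raised when a correlation specification cannot be realised."""


@dataclass(frozen=True)
class CorrelationSpec:
    """Rates and block-structured pairwise correlations of one population.

    Parameters
    ----------
    group_sizes
        Number of neurons per group.
    rate
        Stationary firing rate, spikes/s, shared by all neurons.
    within_corr
        Correlation coefficient between neurons of the same group; scalar
        or one value per group.  Must lie in [0, 1).
    between_corr
        Correlation coefficient across groups; scalar (applied to all
        pairs), or a symmetric (n_groups, n_groups) array whose diagonal is
        ignored.
    """

    group_sizes: tuple[int, ...]
    rate: float
    within_corr: tuple[float, ...]
    between_corr: tuple[tuple[float, ...], ...] = field(default=None)  # type: ignore[assignment]

    def __init__(self, group_sizes, rate, within_corr=0.0, between_corr=0.0):
        sizes = tuple(int(n) for n in np.atleast_1d(group_sizes))
        if any(n <= 0 for n in sizes):
            raise ValueError("group sizes must be positive")
        if rate <= 0:
            raise ValueError("rate must be positive (spikes/s)")
        k = len(sizes)
        w = np.broadcast_to(np.asarray(within_corr, float), (k,)).copy()
        b = np.asarray(between_corr, float)
        if b.ndim == 0:
            b = np.full((k, k), float(b))
        if b.shape != (k, k):
            raise ValueError("between_corr must be scalar or (n_groups, n_groups)")
        b = b.copy()
        np.fill_diagonal(b, 0.0)
        if not np.allclose(b, b.T):
            raise ValueError("between_corr must be symmetric")
        object.__setattr__(self, "group_sizes", sizes)
        object.__setattr__(self, "rate", float(rate))
        object.__setattr__(self, "within_corr", tuple(float(x) for x in w))
        object.__setattr__(self, "between_corr", tuple(tuple(row) for row in b))
        self._validate()

    # -- admissibility -------------------------------------------------
    def _validate(self) -> None:
        w = np.asarray(self.within_corr)
        b = np.asarray(self.between_corr)
        if np.any(w < 0) or np.any(w >= 1):
            raise AdmissibilityError("within-group correlations must lie in [0, 1)")
        if np.any(b < 0) or np.any(b >= 1):
            raise AdmissibilityError("between-group correlations must lie in [0, 1)")
        k = len(self.group_sizes)
        for g in range(k):
            for h in range(g + 1, k):
                if b[g, h] > min(w[g], w[h]) + 1e-12:
                    raise AdmissibilityError(
                        f"between_corr[{g},{h}]={b[g, h]:g} exceeds "
                        f"min(within_corr[{g}], within_corr[{h}])="
                        f"{min(w[g], w[h]):g}"
                    )
        load = b.sum(axis=1)
        for g in range(k):
            if load[g] > w[g] + 1e-12:
                raise AdmissibilityError(
                    f"group {g}: sum of between-group correlations "
                    f"({load[g]:g}) exceeds within_corr[{g}]={w[g]:g}; the "
                    "latent-source construction cannot realise this spec"
                )

    # -- convenience ---------------------------------------------------
    @property
    def n_neurons(self) -> int:
        return int(sum(self.group_sizes))

    @property
    def group_offsets(self) -> tuple[int, ...]:
        return tuple(np.concatenate([[0], np.cumsum(self.group_sizes)[:-1]]).astype(int))

    def correlated_pairs(self) -> list[tuple[int, int, float]]:
        """(g, h, c_gh) for every group pair with nonzero correlation."""
        b = np.asarray(self.between_corr)
        k = len(self.group_sizes)
        return [
            (g, h, b[g, h])
            for g in range(k)
            for h in range(g + 1, k)
            if b[g, h] > 0.0
        ]


@dataclass
class SpikeTrainSet:
    """Binned binary spike trains for one labelled population."""

    bins: np.ndarray          # uint8, (n_neurons, n_bins)
    dt: float                 # ms per bin
    labels: np.ndarray        # population tag per neuron, e.g. 'E' / 'I'
    duration: float           # ms

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins, dtype=np.uint8)
        if self.bins.ndim != 2:
            raise ValueError("bins must be 2-D (neurons x time bins)")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not np.isclose(self.duration, self.bins.shape[1] * self.dt):
            raise ValueError("duration must equal n_bins * dt")
        if self.bins.max(initial=0) > 1:
            raise ValueError("bins must be binary")
        self.labels = np.asarray(self.labels)
        if self.labels.shape[0] != self.bins.shape[0]:
            raise ValueError("one label per neuron required")

    @property
    def n_neurons(self) -> int:
        return self.bins.shape[0]

    @property
    def n_bins(self) -> int:
        return self.bins.shape[1]

    def spike_times(self, neuron: int) -> np.ndarray:
        """Spike times of one neuron, ms (bin left edges)."""
        return np.flatnonzero(self.bins[neuron]) * self.dt

    # -- serialization -------------------------------------------------
    def to_hdf5(self, path, group: str = "spike_trains") -> None:
        import h5py

        with h5py.File(path, "a") as f:
            if group in f:
                del f[group]
            g = f.create_group(group)
            g.create_dataset("packed_bins", data=np.packbits(self.bins, axis=1))
            g.attrs["n_bins"] = self.n_bins
            g.attrs["dt_ms"] = self.dt
            g.attrs["duration_ms"] = self.duration
            g.create_dataset(
                "labels", data=np.asarray(self.labels, dtype="S8")
            )

    @classmethod
    def from_hdf5(cls, path, group: str = "spike_trains") -> "SpikeTrainSet":
        import h5py

        with h5py.File(path, "r") as f:
            g = f[group]
            n_bins = int(g.attrs["n_bins"])
            bins = np.unpackbits(g["packed_bins"][...], axis=1)[:, :n_bins]
            labels = g["labels"][...].astype("U8")
            return cls(bins=bins, dt=float(g.attrs["dt_ms"]),
                       labels=labels, duration=float(g.attrs["duration_ms"]))

    def to_events_csv(self, path) -> None:
        """Write an event list (neuron_id, spike_time_ms)."""
        import pandas as pd

        neur, t = np.nonzero(self.bins)
        pd.DataFrame(
            {"neuron_id": neur, "spike_time_ms": t * self.dt}
        ).to_csv(path, index=False)


@dataclass
class EmpiricalStats:
    """Measured per-neuron rates and pairwise count correlations."""

    rates: np.ndarray        # spikes/s
    corr: np.ndarray         # pairwise correlation of binned counts
    defined: np.ndarray      # bool mask: False where a neuron never/always fired


# ---------------------------------------------------------------------------
# correlation matrix
# ---------------------------------------------------------------------------

def build_correlation_matrix(spec: CorrelationSpec) -> np.ndarray:
    """Explicit (N, N) correlation matrix implied by a block spec.

    Unit diagonal, ``within_corr[g]`` inside group blocks and
    ``between_corr[g, h]`` across blocks.  The result is checked to be
    positive semidefinite.
    """
    sizes = spec.group_sizes
    n = spec.n_neurons
    grp = np.repeat(np.arange(len(sizes)), sizes)
    w = np.asarray(spec.within_corr)
    b = np.asarray(spec.between_corr)
    block = b.copy()
    block[np.diag_indices_from(block)] = w
    c = block[np.ix_(grp, grp)]
    np.fill_diagonal(c, 1.0)
    min_eig = np.linalg.eigvalsh(c).min()
    if min_eig < -1e-10 * n:
        raise AdmissibilityError(
            f"implied correlation matrix is not PSD (min eigenvalue {min_eig:g})"
        )
    return c


# ---------------------------------------------------------------------------
# sparse Bernoulli helpers
# ---------------------------------------------------------------------------

def _stream(seed: int, kind: int, tag: int, index: int, chunk: int) -> np.random.Generator:
    """Independent substream with a fixed, documented key layout.

    Keys are ``(seed, kind, tag, index, chunk)`` so that adding neurons or
    extending the duration never perturbs previously generated trains.
    """
    return np.random.default_rng(
        np.random.SeedSequence((int(seed), kind, int(tag), int(index), int(chunk)))
    )


def _bernoulli_positions(rng: np.random.Generator, n_bins: int, q: float) -> np.ndarray:
    """Sorted bin indices of a Bernoulli(q) process, sampled via geometric gaps."""
    if q <= 0.0 or n_bins <= 0:
        return np.empty(0, dtype=np.int64)
    out = []
    pos = -1
    est = int(n_bins * q + 6.0 * math.sqrt(n_bins * q) + 16)
    while True:
        gaps = rng.geometric(q, est)
        positions = pos + np.cumsum(gaps)
        keep = positions[positions < n_bins]
        out.append(keep)
        if keep.size < positions.size or positions.size == 0:
            break
        pos = int(positions[-1])
        est = max(16, int((n_bins - pos) * q * 1.5 + 16))
    return np.concatenate(out).astype(np.int64)


def _member(sorted_a: np.ndarray, sorted_b: np.ndarray) -> np.ndarray:
    """Boolean mask: which elements of sorted_a occur in sorted_b."""
    if sorted_b.size == 0:
        return np.zeros(sorted_a.size, dtype=bool)
    idx = np.searchsorted(sorted_b, sorted_a)
    idx = np.minimum(idx, sorted_b.size - 1)
    return sorted_b[idx] == sorted_a


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _chunk_events(
    spec: CorrelationSpec,
    q: float,
    n_bins: int,
    seed: int,
    stream_tag: int,
    chunk_index: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Events (bin, neuron) of one internal chunk, sorted by bin then neuron."""
    k = len(spec.group_sizes)
    w = np.asarray(spec.within_corr)
    pairs = spec.correlated_pairs()

    # latent trains
    group_lat: dict[int, np.ndarray] = {}
    pair_lat: dict[tuple[int, int], np.ndarray] = {}
    pair_load = np.zeros(k)
    for g, h, c in pairs:
        pair_load[g] += c
        pair_load[h] += c
    for g in range(k):
        if w[g] - pair_load[g] > 0.0:
            rng = _stream(seed, _KIND_GROUP, stream_tag, g, chunk_index)
            group_lat[g] = _bernoulli_positions(rng, n_bins, q)
    for p_idx, (g, h, c) in enumerate(pairs):
        rng = _stream(seed, _KIND_PAIR, stream_tag, p_idx, chunk_index)
        pair_lat[(g, h)] = _bernoulli_positions(rng, n_bins, q)

    offsets = spec.group_offsets
    ev_bins: list[np.ndarray] = []
    ev_neur: list[np.ndarray] = []
    for g in range(k):
        a = math.sqrt(max(w[g] - pair_load[g], 0.0))
        # (latent bins, selector lo, selector hi)
        sources: list[tuple[np.ndarray, float, float]] = []
        cum = 0.0
        if a > 0.0:
            sources.append((group_lat[g], 0.0, a))
            cum = a
        for (gg, hh, c) in pairs:
            if g in (gg, hh):
                e = math.sqrt(c)
                sources.append((pair_lat[(gg, hh)], cum, cum + e))
                cum += e
        for j in range(spec.group_sizes[g]):
            neuron = offsets[g] + j
            rng = _stream(seed, _KIND_CHILD, stream_tag, neuron, chunk_index)
            fresh = _bernoulli_positions(rng, n_bins, q)
            if sources:
                cand = np.unique(
                    np.concatenate([s[0] for s in sources] + [fresh])
                )
            else:
                cand = fresh
            u = rng.random(cand.size)
            spike = np.zeros(cand.size, dtype=bool)
            for bins_s, lo, hi in sources:
                spike |= _member(cand, bins_s) & (u >= lo) & (u < hi)
            spike |= _member(cand, fresh) & (u >= cum)
            hits = cand[spike]
            ev_bins.append(hits)
            ev_neur.append(np.full(hits.size, neuron, dtype=np.int64))
    if not ev_bins:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    b = np.concatenate(ev_bins)
    nn = np.concatenate(ev_neur)
    order = np.lexsort((nn, b))
    return b[order], nn[order]


def iter_event_chunks(
    spec: CorrelationSpec,
    duration: float,
    dt: float,
    seed: int,
    stream_tag: int = 0,
    start_chunk: int = 0,
) -> Iterator[tuple[int, int, np.ndarray, np.ndarray]]:
    """Stream spike events chunk by chunk.

    Yields ``(start_bin, n_bins, event_bins, event_neurons)`` with event
    bins local to the chunk.  Chunking is fixed internally (`CHUNK_MS`), so
    the generated trains are a deterministic function of
    ``(spec, dt, seed, stream_tag)`` alone; requesting a longer duration
    extends the trains without altering their common prefix.
    """
    q = _bin_probability(spec.rate, dt)
    bins_per_chunk = int(round(CHUNK_MS / dt))
    total_bins = int(round(duration / dt))
    start = 0
    chunk = start_chunk
    while start < total_bins:
        n = min(bins_per_chunk, total_bins - start)
        # always generate the full chunk and truncate, so that a partial
        # trailing chunk is a prefix of the full one (duration extension
        # never perturbs earlier spikes)
        ev_b, ev_n = _chunk_events(spec, q, bins_per_chunk, seed, stream_tag, chunk)
        if n < bins_per_chunk:
            keep = ev_b < n
            ev_b, ev_n = ev_b[keep], ev_n[keep]
        yield start, n, ev_b, ev_n
        start += n
        chunk += 1


def _bin_probability(rate: float, dt: float) -> float:
    q = rate * dt / 1000.0
    if q >= 1.0:
        raise ValueError(
            f"rate*dt = {q:g} >= 1: no Bernoulli bin probability exists; "
            "decrease dt or the rate"
        )
    if q >= 0.1:
        import warnings

        warnings.warn(
            f"bin spike probability q={q:.3g} >= 0.1: outside the Bernoulli "
            "approximation regime of a Poisson process",
            stacklevel=3,
        )
    return q


def generate_trains(
    spec: CorrelationSpec,
    duration: float,
    dt: float,
    seed: int,
    label: str = "I",
    stream_tag: int = 0,
) -> SpikeTrainSet:
    """Generate a dense binary spike-train matrix for a population.

    Parameters
    ----------
    spec
        Rates and block correlation structure.
    duration, dt
        Total length and bin width, ms.
    seed
        Master seed; all substreams are derived from it with fixed offsets.
    label
        Population tag recorded per neuron ('E' or 'I').
    stream_tag
        Integer distinguishing independently generated populations under
        the same master seed (e.g. excitatory vs inhibitory inputs).
    """
    n_bins = int(round(duration / dt))
    bins = np.zeros((spec.n_neurons, n_bins), dtype=np.uint8)
    for start, n, ev_b, ev_n in iter_event_chunks(spec, duration, dt, seed, stream_tag):
        bins[ev_n, start + ev_b] = 1
    labels = np.full(spec.n_neurons, label)
    return SpikeTrainSet(bins=bins, dt=dt, labels=labels, duration=n_bins * dt)


# ---------------------------------------------------------------------------
# validation statistics
# ---------------------------------------------------------------------------

def empirical_statistics(trains: SpikeTrainSet) -> EmpiricalStats:
    """Per-neuron rates and the pairwise count-correlation matrix.

    Correlations are computed on the binary bin counts at resolution
    ``trains.dt``.  Neurons with constant trains (all zeros or all ones)
    have undefined correlations; the corresponding entries are set to the
    sentinel :data:`UNDEFINED_CORR` and flagged in ``defined``.
    """
    if trains.duration < 1000.0:
        raise ValueError("at least 1 s of data required for stable estimates")
    x = trains.bins.astype(np.float64)
    rates = x.mean(axis=1) * 1000.0 / trains.dt
    sd = x.std(axis=1)
    defined = sd > 0
    corr = np.full((trains.n_neurons, trains.n_neurons), UNDEFINED_CORR)
    if defined.any():
        sub = np.corrcoef(x[defined])
        sub = np.atleast_2d(sub)
        idx = np.flatnonzero(defined)
        corr[np.ix_(idx, idx)] = sub
    np.fill_diagonal(corr, 1.0)
    return EmpiricalStats(rates=rates, corr=corr, defined=defined)


def block_mean_correlations(
    stats: EmpiricalStats, spec: CorrelationSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Average measured correlations over the blocks of a spec.

    Returns (within means per group, between means per group pair); handy
    for checking the generator against its own targets.
    """
    k = len(spec.group_sizes)
    grp = np.repeat(np.arange(k), spec.group_sizes)
    within = np.zeros(k)
    between = np.zeros((k, k))
    for g in range(k):
        idx = np.flatnonzero(grp == g)
        if idx.size > 1:
            block = stats.corr[np.ix_(idx, idx)]
            off = block[~np.eye(idx.size, dtype=bool)]
            within[g] = off[off != UNDEFINED_CORR].mean()
        for h in range(k):
            if h == g:
                continue
            jdx = np.flatnonzero(grp == h)
            block = stats.corr[np.ix_(idx, jdx)].ravel()
            between[g, h] = block[block != UNDEFINED_CORR].mean()
    return within, between
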