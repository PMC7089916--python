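"""Constrained permutations of scan data and the scan bootstrap.

The null model randomizes *who* is in each subgroup while preserving the
structure that the sampling design imposes on the data stream:

* the per-scan subgroup (party) size,
* the focal individual of every scan (who is a member by definition),
* each individual's overall occurrence likelihood (used as the sampling
  weight for the non-focal slots), and
* temporal autocorrelation: maximal runs of consecutive identical scans in
  the observed data stay identical within each randomized realization.

Non-focal slots are filled by weighted sampling *without* replacement,
i.e. successive draws with renormalization.  Internally this is realized
via exponential/Gumbel keys (Efraimidis-Spirakis), which is distributionally
identical to the sequential scheme and vectorizes over all runs at once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator, Mapping, Sequence

import numpy as np

from .scan_data import ScanDataset, occurrence_frequency, _pack_rows

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Run:
    """Maximal block of consecutive scans with identical composition and focal."""

    start: int
    length: int
    focal_idx: int
    composition: frozenset

    @property
    def stop(self) -> int:
        return self.start + self.length


def collapse_runs(ds: ScanDataset) -> list:
    """Split the scan sequence into maximal identical runs.

    A run breaks when either the present set or the focal changes; a
    composition repeated across a focal change counts as two runs
    (autocorrelation arises within follows).  Concatenating the runs
    reproduces the scan order.
    """
    bounds = _run_bounds(ds)
    ids = ds.ids
    out = []
    for start, stop in zip(bounds[:-1], bounds[1:]):
        comp = frozenset(ids[j] for j in np.flatnonzero(ds.presence[start]))
        out.append(Run(int(start), int(stop - start), int(ds.focal_idx[start]), comp))
    return out


def _run_bounds(ds: ScanDataset) -> np.ndarray:
    s = ds.n_scans
    if s == 0:
        return np.array([0])
    change = np.zeros(s, dtype=bool)
    change[0] = True
    if s > 1:
        diff = (ds.presence[1:] != ds.presence[:-1]).any(axis=1)
        diff |= ds.focal_idx[1:] != ds.focal_idx[:-1]
        change[1:] = diff
    starts = np.flatnonzero(change)
    return np.append(starts, s)


def _weight_vector(ds: ScanDataset, weights, weight_mode: str) -> np.ndarray:
    if weights is None:
        if weight_mode == "raw":
            weights = occurrence_frequency(ds)
        elif weight_mode == "exclude_focal_scans":
            # occurrence computed only over scans where the individual was not focal
            n = len(ds.roster)
            w = np.empty(n)
            for j in range(n):
                not_focal = ds.focal_idx != j
                w[j] = ds.presence[not_focal, j].mean() if not_focal.any() else 0.0
            return w
        else:
            raise ValueError(f"unknown weight_mode {weight_mode!r}")
    if isinstance(weights, Mapping):
        return np.array([weights[i] for i in ds.ids], dtype=float)
    return np.asarray(weights, dtype=float)


def _permute_runs(
    run_presence: np.ndarray,
    run_focal: np.ndarray,
    weights: np.ndarray,
    rng: np.random.Generator,
    run_starts: np.ndarray | None = None,
) -> np.ndarray:
    """Redraw each run's composition under the constraint set (vectorized).

    Gumbel keys ``log w + G`` ranked per run give weighted sampling without
    replacement among the non-focal candidates; the top ``size - 1`` keys
    are selected and the focal re-added.
    """
    r, n = run_presence.shape
    sizes = run_presence.sum(axis=1)
    with np.errstate(divide="ignore"):
        logw = np.log(weights)
    positive = weights > 0

    # feasibility: enough positive-weight non-focal candidates per run
    avail = positive.sum() - positive[run_focal].astype(int)
    short = sizes - 1 > avail
    if short.any():
        bad = int(np.flatnonzero(short)[0])
        where = f"run starting at scan index {run_starts[bad]}" if run_starts is not None else f"run {bad}"
        raise ValueError(
            f"cannot permute {where}: size {int(sizes[bad])} exceeds "
            f"{int(avail[bad])} positive-weight candidates plus the focal"
        )

    keys = logw[None, :] + rng.gumbel(size=(r, n))
    keys[np.arange(r), run_focal] = -np.inf  # focal handled separately
    order = np.argsort(-keys, axis=1)
    ranks = np.empty_like(order)
    rows = np.arange(r)[:, None]
    ranks[rows, order] = np.arange(n)[None, :]
    out = ranks < (sizes - 1)[:, None]
    out[np.arange(r), run_focal] = True
    return out


def permute_dataset(
    ds: ScanDataset,
    weights=None,
    seed=None,
    rng: np.random.Generator | None = None,
    weight_mode: str = "raw",
) -> ScanDataset:
    """One constrained permutation of the dataset.

    ``weights`` defaults to the observed occurrence frequencies; pass a
    mapping or array to override.  Scan order, timestamps, sizes, focal
    sequence and run structure are preserved exactly.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    w = _weight_vector(ds, weights, weight_mode)
    bounds = _run_bounds(ds)
    starts = bounds[:-1]
    run_presence = ds.presence[starts]
    run_focal = ds.focal_idx[starts]
    new_runs = _permute_runs(run_presence, run_focal, w, rng, run_starts=starts)
    lengths = np.diff(bounds)
    presence = np.repeat(new_runs, lengths, axis=0)
    return ds.replace_presence(presence)


# -- ensembles ---------------------------------------------------------------


@dataclass
class PermutationEnsemble:
    """Sufficient statistics of B constrained permutations of one dataset.

    Per realization the ensemble retains the composition entropy, per-dyad
    SRI, and per-member occurrence frequency; the pooled composition
    multiset (run compositions weighted by run length) across all
    realizations is kept for KL/JS comparisons.  Any single realization can
    be regenerated as a full :class:`ScanDataset` from the master seed.
    """

    source: ScanDataset
    B: int
    seed: int | None
    dyads: list                      # (id_a, id_b) pairs, upper-triangle order
    sri: np.ndarray                  # (B, n_dyads)
    entropies: np.ndarray            # (B,) bits
    occ_freq: np.ndarray             # (B, n)
    pooled_keys: np.ndarray          # packed unique compositions across ensemble
    pooled_counts: np.ndarray        # scan-weighted counts per pooled key
    weight_mode: str = "raw"

    @property
    def n_scans(self) -> int:
        return self.source.n_scans

    def realization(self, b: int) -> ScanDataset:
        """Regenerate realization ``b`` (deterministic in the master seed)."""
        if not 0 <= b < self.B:
            raise IndexError(b)
        rng = np.random.default_rng(_spawn_seeds(self.seed, self.B)[b])
        return permute_dataset(self.source, seed=None, rng=rng, weight_mode=self.weight_mode)

    def realizations(self) -> Iterator[ScanDataset]:
        for b in range(self.B):
            yield self.realization(b)


def _normalize_seed(seed):
    """Reduce any seed-like input to a plain int (stable under reuse)."""
    if isinstance(seed, np.random.SeedSequence):
        return int(seed.generate_state(1)[0])
    return seed


def _spawn_seeds(seed, B: int) -> list:
    """Counter-based per-realization seeds from the master seed."""
    return np.random.SeedSequence(_normalize_seed(seed)).spawn(B)


def _dyad_pairs(ids: Sequence[str]):
    iu = np.triu_indices(len(ids), k=1)
    return [(ids[i], ids[j]) for i, j in zip(*iu)], iu


def _entropy_from_counts(counts: np.ndarray) -> float:
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def sri_from_presence(presence: np.ndarray, iu) -> np.ndarray:
    """Vector of simple ratio indices for all dyads from a presence matrix."""
    m = presence.astype(np.float64)
    c = m.T @ m
    n_i = np.diag(c)
    together = c[iu]
    denom = n_i[iu[0]] + n_i[iu[1]] - together
    out = np.zeros_like(together)
    np.divide(together, denom, out=out, where=denom > 0)
    return out


def build_ensemble(
    ds: ScanDataset,
    B: int = 1000,
    seed=None,
    workers: int = 1,
    weight_mode: str = "raw",
    weights=None,
) -> PermutationEnsemble:
    """Generate B constrained permutations and collect their statistics.

    Per-realization seeds are spawned deterministically from the master
    seed, so results are identical whatever the worker count.  The heavy
    state kept per realization is O(n_dyads), not O(n_scans).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    seed = _normalize_seed(seed)
    w = _weight_vector(ds, weights, weight_mode)
    bounds = _run_bounds(ds)
    starts = bounds[:-1]
    lengths = np.diff(bounds).astype(np.float64)
    run_presence = ds.presence[starts]
    run_focal = ds.focal_idx[starts]
    ids = ds.ids
    dyads, iu = _dyad_pairs(ids)
    seeds = _spawn_seeds(seed, B)

    def one(b):
        rng = np.random.default_rng(seeds[b])
        runs = _permute_runs(run_presence, run_focal, w, rng, run_starts=starts)
        m = runs.astype(np.float64)
        weighted = m * lengths[:, None]
        c = weighted.T @ m
        n_i = np.diag(c)
        together = c[iu]
        denom = n_i[iu[0]] + n_i[iu[1]] - together
        sri = np.zeros_like(together)
        np.divide(together, denom, out=sri, where=denom > 0)

        keys = _pack_rows(runs)
        uniq, inv = np.unique(keys, return_inverse=True)
        counts = np.bincount(inv, weights=lengths)
        h = _entropy_from_counts(counts)
        occ = weighted.sum(axis=0) / lengths.sum()
        return sri, h, occ, uniq, counts

    if workers > 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=workers)(delayed(one)(b) for b in range(B))
    else:
        results = [one(b) for b in range(B)]

    sri = np.stack([r[0] for r in results])
    entropies = np.array([r[1] for r in results])
    occ = np.stack([r[2] for r in results])

    all_keys = np.concatenate([r[3] for r in results])
    all_counts = np.concatenate([r[4] for r in results])
    pooled_keys, inv = np.unique(all_keys, return_inverse=True)
    pooled_counts = np.bincount(inv, weights=all_counts)

    return PermutationEnsemble(
        source=ds,
        B=B,
        seed=seed,
        dyads=dyads,
        sri=sri,
        entropies=entropies,
        occ_freq=occ,
        pooled_keys=pooled_keys,
        pooled_counts=pooled_counts,
        weight_mode=weight_mode,
    )


def validate_permutation(observed: ScanDataset, permuted: ScanDataset) -> None:
    """Assert the constraint triple; raises ``AssertionError`` on violation.

    Checks per-scan size, focal membership and identity, unchanged
    timestamps, and the run structure.  Runs are compared at the observed
    boundaries: every observed run must stay internally identical in the
    realization (so the run-length multiset as generated matches the
    observed one), and the realization may not introduce boundaries inside
    an observed run.  Adjacent observed runs are allowed to coincide by
    chance after redrawing — the autocorrelation rule constrains scans
    that were identical in the *observed* data, nothing more.
    """
    assert permuted.n_scans == observed.n_scans, "scan count changed"
    assert np.array_equal(permuted.focal_idx, observed.focal_idx), "focal sequence changed"
    assert np.array_equal(permuted.timestamps, observed.timestamps), "timestamps changed"
    assert np.array_equal(
        permuted.subgroup_sizes(), observed.subgroup_sizes()
    ), "per-scan subgroup size changed"
    rows = np.arange(permuted.n_scans)
    assert permuted.presence[rows, permuted.focal_idx].all(), "focal missing from a permuted scan"
    obs_bounds = _run_bounds(observed)
    for start, stop in zip(obs_bounds[:-1], obs_bounds[1:]):
        block = permuted.presence[start:stop]
        assert (block == block[0]).all(), f"observed run at scan {start} broken in realization"
    perm_bounds = set(_run_bounds(permuted).tolist())
    assert perm_bounds <= set(obs_bounds.tolist()), "realization split an observed run"


# -- bootstrap ----------------------------------------------------------------


def bootstrap_scans(ds: ScanDataset, R: int = 1000, seed=None):
    """Scan bootstrap for the precision of dyadic simple ratio indices.

    Resamples scans with replacement R times, recomputes every dyad's SRI
    per replicate (a dyad unseen in a replicate scores 0 by the
    denominator-zero convention) and returns a DataFrame of per-dyad sample
    SDs with the maximum in ``.attrs["max_sd"]``.
    """
    import pandas as pd

    if R < 2:
        raise ValueError("bootstrap requires R >= 2")
    rng = np.random.default_rng(seed)
    ids = ds.ids
    dyads, iu = _dyad_pairs(ids)
    s = ds.n_scans
    m = ds.presence.astype(np.float64)
    total = np.zeros(len(dyads))
    total_sq = np.zeros(len(dyads))
    for _ in range(R):
        idx = rng.integers(0, s, s)
        mb = m[idx]
        c = mb.T @ mb
        n_i = np.diag(c)
        together = c[iu]
        denom = n_i[iu[0]] + n_i[iu[1]] - together
        sri = np.zeros_like(together)
        np.divide(together, denom, out=sri, where=denom > 0)
        total += sri
        total_sq += sri * sri
    var = (total_sq - total * total / R) / (R - 1)
    sd = np.sqrt(np.clip(var, 0.0, None))
    out = pd.DataFrame(
        {"id_a": [a for a, _ in dyads], "id_b": [b for _, b in dyads], "sri_sd_boot": sd}
    )
    out.attrs["max_sd"] = float(sd.max()) if len(sd) else 0.0
    return out
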