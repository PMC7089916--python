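"""Dyad-level association: simple ratio index, PAV, significance, precision.

The simple ratio index for a dyad is SRI = P_AB / (P_A + P_B + P_AB) where
P_AB counts scans with both members and P_A, P_B count scans with exactly
one of them (the standard definition: the lone-sighting counts exclude
joint sightings, so the index spans [0, 1]).  A strict-literal mode, in
which P_A and P_B include joint sightings and the index is bounded below
1, is available behind ``literal=True`` for comparison only.

The pairwise affinity value (PAV) is observed SRI minus the permutation-
expected SRI, in [-1, 1]; positive values mean the dyad associates more
than expected.  A dyad is a *significant associate* when its observed SRI
strictly exceeds more than (1 - alpha) * B of the B permuted values (for
B = 1000 and alpha = 0.05: higher than 950 of 1000; ties count against
significance).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scan_data import ScanDataset
from .null_model import PermutationEnsemble, _dyad_pairs, bootstrap_scans

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DyadCounts:
    """Sighting counts for one unordered dyad."""

    id_a: str
    id_b: str
    n_together: int
    n_a_only: int
    n_b_only: int
    n_scans: int

    def __post_init__(self):
        if min(self.n_together, self.n_a_only, self.n_b_only) < 0:
            raise ValueError("counts must be nonnegative")
        if self.n_together + self.n_a_only + self.n_b_only > self.n_scans:
            raise ValueError("counts exceed the number of scans")


def dyad_counts(ds: ScanDataset) -> list:
    """Exact sighting counts for every unordered pair of roster members."""
    m = ds.presence.astype(np.int64)
    c = m.T @ m                      # joint sightings
    n_i = np.diag(c)                 # total sightings per member
    ids = ds.ids
    dyads, iu = _dyad_pairs(ids)
    out = []
    for (a, b), i, j in zip(dyads, *iu):
        t = int(c[i, j])
        out.append(
            DyadCounts(
                id_a=a,
                id_b=b,
                n_together=t,
                n_a_only=int(n_i[i]) - t,
                n_b_only=int(n_i[j]) - t,
                n_scans=ds.n_scans,
            )
        )
    return out


def sri(c: DyadCounts, literal: bool = False) -> float:
    """Simple ratio index of one dyad; 0 when the dyad was never seen."""
    if literal:
        denom = (c.n_a_only + c.n_together) + (c.n_b_only + c.n_together) + c.n_together
    else:
        denom = c.n_a_only + c.n_b_only + c.n_together
    if denom == 0:
        log.debug("dyad (%s, %s) never observed; SRI set to 0", c.id_a, c.id_b)
        return 0.0
    return c.n_together / denom


def expected_sri(ens: PermutationEnsemble):
    """Per-dyad mean permuted SRI and the full (B, n_dyads) matrix."""
    return ens.sri.mean(axis=0), ens.sri


def pav(sri_obs: float, sri_exp: float) -> float:
    """Pairwise affinity value: observed minus expected SRI, in [-1, 1]."""
    return sri_obs - sri_exp


def significance(sri_obs: float, permuted: np.ndarray, alpha: float = 0.05):
    """Permutation rank and significant-associate flag for one dyad.

    ``p_rank`` counts permutations whose SRI is strictly below the observed
    value; the flag requires ``p_rank > (1 - alpha) * B`` (strict), so ties
    with permuted values count against significance.
    """
    permuted = np.asarray(permuted)
    B = len(permuted)
    if B < 1:
        raise ValueError("need at least one permutation")
    p_rank = int((permuted < sri_obs).sum())
    return p_rank, p_rank > (1.0 - alpha) * B


def dyad_table(
    ds: ScanDataset,
    ens: PermutationEnsemble,
    boot: pd.DataFrame | None = None,
    alpha: float = 0.05,
    R_boot: int | None = None,
    seed=None,
) -> pd.DataFrame:
    """Assemble the per-dyad association table for one season.

    Columns: ``id_a, id_b, season, sri_obs, sri_exp, pav, p_rank,
    significant, sri_sd_boot``.  Pass a precomputed ``boot`` frame from
    :func:`assocpat.null_model.bootstrap_scans`, or set ``R_boot`` to run
    it here; otherwise the SD column is NaN.
    """
    counts = dyad_counts(ds)
    obs = np.array([sri(c) for c in counts])
    exp_mean, perm = expected_sri(ens)
    B = ens.B
    p_rank = (perm < obs[None, :]).sum(axis=0)
    sig = p_rank > (1.0 - alpha) * B

    if boot is None and R_boot is not None:
        boot = bootstrap_scans(ds, R=R_boot, seed=seed)

    out = pd.DataFrame(
        {
            "id_a": [c.id_a for c in counts],
            "id_b": [c.id_b for c in counts],
            "season": ds.roster.season,
            "sri_obs": obs,
            "sri_exp": exp_mean,
            "pav": obs - exp_mean,
            "p_rank": p_rank.astype(int),
            "significant": sig,
        }
    )
    if boot is not None:
        out = out.merge(boot, on=["id_a", "id_b"], how="left")
    else:
        out["sri_sd_boot"] = np.nan
    return out
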