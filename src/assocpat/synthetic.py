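"""Synthetic scan-sample generator with known ground truth.

The study system is observational — there is no generative model to copy —
so this module is an artifact of the package: it fabricates datasets whose
*structure* matches field scan data (focal-follow blocks, temporal
autocorrelation, right-skewed subgroup sizes, gregariousness heterogeneity)
while exposing the latent parameters (dyadic affinities, gregariousness
weights, ranks) so that recovery and calibration tests have an oracle.

Defaults emulate one field season: a roster of 30 weaned individuals,
~5000 scans in 1-h focal follows of four 15-min scans, mean subgroup size 6
with a maximum of 17, and a small probability that consecutive scans within
a follow repeat the previous composition exactly.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
from scipy import stats

from .scan_data import Individual, ScanDataset, SeasonRoster

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AffinityEffects:
    """Log-weight effect sizes injected into the latent dyadic affinity.

    ``kin``: shared-matriline dyads; ``rank_similarity``: scales with
    ``1 - |rank_i - rank_j|``; ``same_sex_subadult``: same-sex dyads of two
    subadults; ``mixed_sex_adult``: adult female-male dyads;
    ``both_infants``: both members are mothers of newborns.
    """

    kin: float = 0.0
    rank_similarity: float = 0.0
    same_sex_subadult: float = 0.0
    mixed_sex_adult: float = 0.0
    both_infants: float = 0.0

    def __post_init__(self):
        for name, v in asdict(self).items():
            if not np.isfinite(v):
                raise ValueError(f"affinity effect {name} must be finite")


@dataclass(frozen=True)
class SyntheticConfig:
    n_individuals: int = 30
    sex_ratio: float = 0.55          # proportion female
    n_matrilines: int = 8
    prop_subadult: float = 0.3
    prop_mothers_with_infant: float = 0.3
    n_scans: int = 5000
    follow_block: int = 4            # scans per 1-h focal follow
    size_distribution: tuple = ("nbinom", {"mean": 5.0, "shape": 10.0})  # of (size - 1)
    max_size: int = 17
    gregariousness_sd: float = 0.3
    autocorr_prob: float = 0.1
    affinity_effects: AffinityEffects = field(default_factory=AffinityEffects)
    season: str = "2014/5"
    start_year: int = 2014
    seed: int = 0

    def __post_init__(self):
        for name in ("sex_ratio", "prop_subadult", "prop_mothers_with_infant", "autocorr_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_scans < 1:
            raise ValueError("n_scans must be >= 1")
        if self.follow_block < 1:
            raise ValueError("follow_block must be >= 1")
        if self.n_matrilines > self.n_individuals:
            raise ValueError("n_matrilines cannot exceed n_individuals")
        if isinstance(self.affinity_effects, Mapping):
            object.__setattr__(self, "affinity_effects", AffinityEffects(**self.affinity_effects))


@dataclass
class GroundTruth:
    """Latent parameters behind a synthetic dataset (the recovery oracle)."""

    roster: SeasonRoster
    matriline: np.ndarray            # (n,) int matriline label per member
    gregariousness: np.ndarray       # (n,) log-weights
    rank: np.ndarray                 # (n,) standardized rank in [0, 1]
    affinity: np.ndarray             # (n, n) symmetric log-weight matrix, zero diagonal
    config: SyntheticConfig

    def kin_matrix(self) -> np.ndarray:
        same = self.matriline[:, None] == self.matriline[None, :]
        np.fill_diagonal(same, False)
        return same

    def to_json(self, path) -> None:
        ids = self.roster.ids
        payload = {
            "season": self.roster.season,
            "ids": list(ids),
            "matriline": self.matriline.tolist(),
            "gregariousness": self.gregariousness.tolist(),
            "rank": self.rank.tolist(),
            "affinity": self.affinity.tolist(),
            "config": _config_dict(self.config),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _config_dict(cfg: SyntheticConfig) -> dict:
    d = asdict(cfg)
    d["size_distribution"] = [cfg.size_distribution[0], dict(cfg.size_distribution[1])]
    return d


# -- roster ------------------------------------------------------------------


def generate_roster(cfg: SyntheticConfig, rng: np.random.Generator | None = None):
    """Build an attributed roster plus its ground-truth latent parameters.

    Matrilines partition the roster; each multi-member matriline gets a
    female adult dam who is recorded as ``mother_id`` of the other members,
    so kinship (mother-offspring or maternal siblings) coincides with
    shared matriline membership.  Standardized ranks are uniformly spaced
    on [0, 1] in random order.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n = cfg.n_individuals
    ids = [f"ID{k:02d}" for k in range(n)]

    matriline = np.sort(np.arange(n) % cfg.n_matrilines)
    rng.shuffle(matriline)
    # dam index per matriline with >= 2 members
    dam_of = {}
    for m in range(cfg.n_matrilines):
        members = np.flatnonzero(matriline == m)
        if len(members) >= 2:
            dam_of[m] = int(members[0])

    sex = np.empty(n, dtype=object)
    dams = set(dam_of.values())
    n_female = int(round(n * cfg.sex_ratio))
    sex[list(dams)] = "female"
    rest = [i for i in range(n) if i not in dams]
    need_f = max(0, n_female - len(dams))
    rng.shuffle(rest)
    for i in rest[:need_f]:
        sex[i] = "female"
    for i in rest[need_f:]:
        sex[i] = "male"

    # subadults drawn from non-dams
    n_sub = int(round(cfg.prop_subadult * n))
    sub_pool = [i for i in range(n) if i not in dams]
    rng.shuffle(sub_pool)
    subadult = set(sub_pool[:n_sub])

    birth_year = np.empty(n, dtype=int)
    for i in range(n):
        if i in subadult:
            hi = 5 if sex[i] == "female" else 7
            age = int(rng.integers(4, hi + 1))
        else:
            lo = 6 if sex[i] == "female" else 8
            age = int(rng.integers(lo, 19))
        birth_year[i] = cfg.start_year - age

    adult_females = [i for i in range(n) if sex[i] == "female" and i not in subadult]
    with_infant = {i for i in adult_females if rng.random() < cfg.prop_mothers_with_infant}

    members = []
    for i in range(n):
        m = matriline[i]
        dam = dam_of.get(m)
        members.append(
            Individual(
                id=ids[i],
                sex=sex[i],
                birth_year=int(birth_year[i]),
                mother_id=ids[dam] if dam is not None and dam != i else None,
                infant_years=frozenset({cfg.season}) if i in with_infant else frozenset(),
            )
        )
    roster = SeasonRoster(season=cfg.season, members=tuple(members), start_year=cfg.start_year)

    rank = np.linspace(0.0, 1.0, n) if n > 1 else np.array([1.0])
    rank = rank[rng.permutation(n)]
    greg = rng.normal(0.0, cfg.gregariousness_sd, n) if cfg.gregariousness_sd > 0 else np.zeros(n)

    gt = GroundTruth(
        roster=roster,
        matriline=matriline,
        gregariousness=greg,
        rank=rank,
        affinity=np.zeros((n, n)),
        config=cfg,
    )
    gt.affinity = build_affinity(roster, cfg.affinity_effects, rank=rank, kin=gt.kin_matrix())
    return roster, gt


def build_affinity(
    roster: SeasonRoster,
    effects: AffinityEffects,
    rank: np.ndarray,
    kin: np.ndarray,
) -> np.ndarray:
    """Latent symmetric affinity matrix from the configured effects."""
    n = len(roster)
    sex = np.array([m.sex for m in roster.members])
    age = np.array([roster.age_class_of(m.id) for m in roster.members])
    infant = np.array([roster.has_infant(m.id) for m in roster.members])

    aff = np.zeros((n, n))
    aff += effects.kin * kin
    aff += effects.rank_similarity * (1.0 - np.abs(rank[:, None] - rank[None, :]))
    same_sex = sex[:, None] == sex[None, :]
    both_sub = (age[:, None] == "subadult") & (age[None, :] == "subadult")
    both_adult = (age[:, None] == "adult") & (age[None, :] == "adult")
    aff += effects.same_sex_subadult * (same_sex & both_sub)
    aff += effects.mixed_sex_adult * (~same_sex & both_adult)
    aff += effects.both_infants * (infant[:, None] & infant[None, :])
    np.fill_diagonal(aff, 0.0)
    return aff


# -- subgroup sizes ------------------------------------------------------------


def _size_probs(cfg: SyntheticConfig) -> np.ndarray:
    """Probability table over subgroup sizes 1..max (truncated support)."""
    cap = min(cfg.max_size, cfg.n_individuals)
    if cfg.max_size > cfg.n_individuals:
        warnings.warn(
            f"size distribution support truncated at roster size {cfg.n_individuals}",
            stacklevel=2,
        )
    name, params = cfg.size_distribution
    extra = np.arange(cap)  # members beyond the focal: size = 1 + extra
    if name == "nbinom":
        mean, shape = params["mean"], params["shape"]
        p = shape / (shape + mean)
        pmf = stats.nbinom.pmf(extra, shape, p)
    elif name == "poisson":
        pmf = stats.poisson.pmf(extra, params["mu"])
    elif name == "constant":
        pmf = (extra == params["value"] - 1).astype(float)
    elif name == "uniform":
        pmf = ((extra + 1 >= params["low"]) & (extra + 1 <= params["high"])).astype(float)
    else:
        raise ValueError(f"unknown size distribution {name!r}")
    total = pmf.sum()
    if total <= 0:
        raise ValueError("size distribution has no mass on the truncated support")
    return pmf / total


# -- scan generation -----------------------------------------------------------


def generate_scan_dataset(cfg: SyntheticConfig):
    """Generate a full season of scans; returns ``(ScanDataset, GroundTruth)``.

    Scans come in focal-follow blocks: the focal cycles through a freshly
    shuffled roster order every full pass, holding each focal for
    ``follow_block`` consecutive scans.  Within a block, each scan repeats
    the previous composition with probability ``autocorr_prob``; otherwise
    a subgroup size is drawn and the non-focal slots are filled by
    sequential weighted sampling without replacement, with log-weight
    ``gregariousness_j + mean affinity of j to the already-selected set``.
    Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    roster, gt = generate_roster(cfg, rng)
    n = cfg.n_individuals
    aff = gt.affinity
    greg = gt.gregariousness
    size_probs = _size_probs(cfg)
    sizes_support = np.arange(1, len(size_probs) + 1)
    zero_affinity = not np.any(aff)

    presence = np.zeros((cfg.n_scans, n), dtype=bool)
    focal_idx = np.empty(cfg.n_scans, dtype=np.intp)

    order = rng.permutation(n)
    cursor = 0
    t0 = np.datetime64(f"{cfg.start_year}-10-01T08:00:00", "s")
    timestamps = t0 + np.arange(cfg.n_scans) * np.timedelta64(15 * 60, "s")

    for i in range(cfg.n_scans):
        pos = i % cfg.follow_block
        if pos == 0:
            if cursor >= n:
                order = rng.permutation(n)
                cursor = 0
            focal = int(order[cursor])
            cursor += 1
        focal_idx[i] = focal

        if pos > 0 and rng.random() < cfg.autocorr_prob:
            presence[i] = presence[i - 1]
            continue

        s = int(rng.choice(sizes_support, p=size_probs))
        row = presence[i]
        row[focal] = True
        if s > 1:
            others = np.flatnonzero(~row)
            if zero_affinity:
                # one-shot weighted draw (Gumbel keys == sequential renormalized draws)
                keys = greg[others] + rng.gumbel(size=others.size)
                pick = others[np.argpartition(-keys, s - 2)[: s - 1]]
                row[pick] = True
            else:
                selected = [focal]
                avail = list(others)
                for _ in range(s - 1):
                    w = np.exp(greg[avail] + aff[np.ix_(avail, selected)].mean(axis=1))
                    j = int(rng.choice(len(avail), p=w / w.sum()))
                    selected.append(avail.pop(j))
                row[selected] = True

    ds = ScanDataset(roster, np.arange(cfg.n_scans), timestamps, focal_idx, presence)
    return ds, gt


# -- dyad-year row simulator -----------------------------------------------------


def simulate_dyad_rows(
    n_rows: int,
    seed: int = 0,
    kin_logodds: float = 0.0,
    rank_coef: float = 0.0,
    intercept: float = -1.5,
    kin_pav: float = 0.0,
    rank_pav: float = 0.0,
    pav_sd: float = 0.05,
    kin_prob: float = 0.15,
    n_seasons: int = 3,
):
    """Simulate dyad-year rows straight from the regression model.

    This bypasses the scan pipeline: covariates are drawn at random and the
    binary significant-associate response follows a logistic model with the
    stated coefficients (``rank_coef`` applies to the z-standardized rank
    difference), while the PAV response is Gaussian around a linear
    predictor.  Random-effect variance is zero by construction, so the
    fixed-effects fitter is the correct model.  Used for parameter-recovery
    and null-calibration tests of the assortativity machinery.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    kin = rng.random(n_rows) < kin_prob
    rank_diff = np.abs(rng.random(n_rows) - rng.random(n_rows))
    rank_z = (rank_diff - rank_diff.mean()) / rank_diff.std()
    sex = rng.choice(["female_female", "female_male", "male_male"], n_rows, p=[0.35, 0.45, 0.2])
    age = rng.choice(["adult_adult", "adult_subadult", "subadult_subadult"], n_rows, p=[0.5, 0.35, 0.15])
    infant = rng.choice(["no_no", "yes_no", "yes_yes"], n_rows, p=[0.55, 0.35, 0.1])

    eta = intercept + kin_logodds * kin + rank_coef * rank_z
    p = 1.0 / (1.0 + np.exp(-eta))
    sig = rng.random(n_rows) < p
    pav = kin_pav * kin + rank_pav * rank_z + rng.normal(0.0, pav_sd, n_rows)

    # plausible id bookkeeping so dyad-flip machinery has slots to swap
    a = rng.integers(0, 40, n_rows)
    b = (a + 1 + rng.integers(0, 39, n_rows)) % 40
    id_1 = np.char.add("ID", np.char.zfill(np.minimum(a, b).astype(str), 2))
    id_2 = np.char.add("ID", np.char.zfill(np.maximum(a, b).astype(str), 2))

    return pd.DataFrame(
        {
            "dyad": [f"{x}|{y}" for x, y in zip(id_1, id_2)],
            "season": [f"S{1 + i % n_seasons}" for i in range(n_rows)],
            "id_1": id_1,
            "id_2": id_2,
            "response_sig": sig.astype(int),
            "response_pav": pav,
            "kinship": kin.astype(int),
            "rank_diff": rank_diff,
            "rank_diff_z": rank_z,
            "sex_combo": sex,
            "age_combo": age,
            "infant_combo": infant,
        }
    )
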