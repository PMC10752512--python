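"""Per-platform calibration of sampled parameter sets to reported user totals.

Each platform is fitted separately: ``n_candidates`` parameter sets are
drawn from the sampling distributions of the group-level survey estimates,
each is interpolated to an age profile, and the profile is scored against
the externally reported user totals per age band. The ``n_keep``
lowest-loss candidates form the uncertainty ensemble; means and percentile
intervals of any downstream quantity are taken over this ensemble.

The loss is the sum over target bands of squared relative errors in band
user counts. The search is a seeded best-of-N random search: candidate
``i`` of platform ``pid`` uses the independent substream
``SeedSequence((seed, crc32(pid), i))``, so fits are reproducible,
order-independent across platforms, and parallelizable by contract. A
different search strategy can be supplied through the ``sampler`` hook
without changing any downstream contract.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .age_model import (AgeProfile, ParameterSet, band_knots, _curve,
                        ensure_child_minutes, sample_group_estimates)
from .tables import (PlatformInputs, PopulationTable, RunConfig, UserTotal,
                     ValidationError)

__all__ = ["EnsembleMember", "FittedEnsemble", "loss", "band_user_matrix",
           "candidate_rng", "fit_platform"]

#: draws a candidate parameter set: (candidate_index, rng) -> ParameterSet
Sampler = Callable[[int, np.random.Generator], ParameterSet]


@dataclass(frozen=True)
class EnsembleMember:
    params: ParameterSet
    profile: AgeProfile
    loss: float


@dataclass(frozen=True)
class FittedEnsemble:
    """The retained best-fitting parameter sets for one platform, sorted
    by loss ascending."""

    platform_id: str
    members: tuple[EnsembleMember, ...]
    n_candidates_evaluated: int
    seed: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", tuple(self.members))
        losses = self.losses
        if np.any(np.diff(losses) < 0):
            raise ValidationError("ensemble members must be sorted by loss")

    def __len__(self) -> int:
        return len(self.members)

    @property
    def losses(self) -> np.ndarray:
        return np.array([m.loss for m in self.members], dtype=float)

    @property
    def profiles(self) -> list[AgeProfile]:
        return [m.profile for m in self.members]

    def to_dict(self) -> dict:
        return {
            "platform_id": self.platform_id,
            "seed": self.seed,
            "n_candidates_evaluated": self.n_candidates_evaluated,
            "losses": [m.loss for m in self.members],
            "prevalence_draws": [m.params.prevalence_draws.tolist()
                                 for m in self.members],
            "minutes_draws": [m.params.minutes_draws.tolist()
                              for m in self.members],
            "candidate_labels": [m.params.rng_state_label for m in self.members],
        }


def _platform_tag(platform_id: str) -> int:
    return zlib.crc32(platform_id.encode("utf-8"))


def candidate_rng(seed: int, platform_id: str, i: int) -> np.random.Generator:
    """Independent, order-free random substream for candidate ``i`` of a
    platform: keyed on (run seed, platform id, candidate counter)."""
    ss = np.random.SeedSequence((seed, _platform_tag(platform_id), i))
    return np.random.default_rng(ss)


def band_user_matrix(targets: Sequence[UserTotal],
                     population: PopulationTable) -> np.ndarray:
    """Aggregation matrix B with ``B[t, a] = population_a`` for ages in
    target band t, so that ``B @ p`` gives modeled band user totals."""
    n_ages = population.counts.size
    B = np.zeros((len(targets), n_ages))
    for t, target in enumerate(targets):
        band = target.band
        if band.hi >= n_ages:
            raise ValidationError(
                f"target band {band.label} outside population range")
        B[t, band.lo:band.hi + 1] = population.counts[band.lo:band.hi + 1]
    return B


def _loss_terms(modeled: np.ndarray, targets_users: np.ndarray) -> np.ndarray:
    """Squared relative errors per band; zero-target bands are scored
    against the mean of the nonzero targets to avoid division by zero."""
    nz = targets_users > 0
    if not np.any(nz):
        raise ValidationError("loss: all calibration targets are zero")
    ref = targets_users[nz].mean()
    denom = np.where(nz, targets_users, ref)
    # bands are the last axis, so the target vector broadcasts over candidates
    rel = modeled - np.where(nz, targets_users, 0.0)
    return (rel / denom) ** 2


def loss(profile: AgeProfile, population: PopulationTable,
         targets: Sequence[UserTotal]) -> float:
    """Calibration loss of one profile: sum over target bands of
    ``((modeled_band_users - target_users) / target_users)**2``. Zero iff
    every band total matches its target exactly."""
    if len(targets) == 0:
        raise ValidationError("loss: no calibration targets")
    B = band_user_matrix(targets, population)
    modeled = B @ profile.p
    users = np.array([t.users for t in targets], dtype=float)
    return float(_loss_terms(modeled, users).sum())


def fit_platform(inputs: PlatformInputs, population: PopulationTable,
                 config: RunConfig,
                 sampler: Sampler | None = None) -> FittedEnsemble:
    """Fit one platform by seeded random search.

    Draws ``config.n_candidates`` parameter sets (via ``sampler`` or the
    default truncated-normal draws from the survey estimates), builds and
    scores every age profile, and retains the ``config.n_keep`` smallest
    losses (ties broken by candidate index, so the result is
    deterministic)."""
    if config.n_candidates < config.n_keep:
        raise ValidationError("n_candidates < n_keep")
    pid = inputs.platform_id
    prevalence_bands = inputs.use_prevalence
    minutes_bands = ensure_child_minutes(inputs.minutes, config)

    candidates: list[ParameterSet] = []
    for i in range(config.n_candidates):
        rng = candidate_rng(config.seed, pid, i)
        if sampler is not None:
            ps = sampler(i, rng)
        else:
            ps = ParameterSet(
                platform_id=pid,
                prevalence_draws=sample_group_estimates(
                    prevalence_bands, rng, kind="proportion"),
                minutes_draws=sample_group_estimates(
                    minutes_bands, rng, kind="minutes"),
                rng_state_label=f"({config.seed},{pid},{i})",
            )
        candidates.append(ps)

    ages = np.arange(config.age_max + 1, dtype=float)
    P = np.column_stack([ps.prevalence_draws for ps in candidates])
    M = np.column_stack([ps.minutes_draws for ps in candidates])
    p_mat = _curve(band_knots(prevalence_bands, config.age_max), P, ages,
                   0.0, 1.0)
    m_mat = _curve(band_knots(minutes_bands, config.age_max), M, ages,
                   0.0, np.inf)

    if len(inputs.group_user_totals) == 0:
        raise ValidationError(f"{pid}: no calibration targets")
    B = band_user_matrix(inputs.group_user_totals, population)
    users_targets = np.array([t.users for t in inputs.group_user_totals],
                             dtype=float)
    modeled = B @ p_mat                       # (n_targets, n_candidates)
    losses = _loss_terms(modeled.T, users_targets).sum(axis=1)

    keep = np.argsort(losses, kind="stable")[:config.n_keep]
    members = tuple(
        EnsembleMember(
            params=candidates[i],
            profile=AgeProfile(platform_id=pid, p=p_mat[:, i], m=m_mat[:, i]),
            loss=float(losses[i]),
        )
        for i in keep)
    return FittedEnsemble(platform_id=pid, members=members,
                          n_candidates_evaluated=config.n_candidates,
                          seed=config.seed)
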