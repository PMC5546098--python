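"""Synthetic chemical universes with the statistical structure the analysis
assumes.

Real registration datasets cannot be redistributed, so every downstream
module is exercised on generated universes that emulate the relevant
features: clustered binary fingerprints (cluster members are independent
per-bit corruptions of a cluster prototype, so within-cluster Tanimoto
similarity is controlled by the bit-flip rate), cluster-dependent sensitizer
prevalence around a global rate of about 21%, structural-alert flags drawn
with configurable class-conditional probabilities, lognormal molecular
weights, and repeated studies per chemical whose outcomes flip away from the
true label with a configurable per-assay error rate.

Generation is fully deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io_model import (AlertFlags, ChemicalRecord, NON_SENSITIZER,
                       OUTCOME_INCONCLUSIVE, OUTCOME_NON, OUTCOME_SENS,
                       SENSITIZER, StudyRecord)

#: class-conditional alert probabilities (p given sensitizer, p given non-)
#: chosen so overall prevalences at 21% sensitizers echo the alert rates
#: typical of an industrial chemical universe (MA ~13%, SN2 ~5%, SB ~8%,
#: AA ~9%, SNAr ~0.7%)
DEFAULT_ALERT_PROBS: dict[str, tuple[float, float]] = {
    "sn2": (0.09, 0.04),
    "ma": (0.30, 0.09),
    "sb": (0.15, 0.055),
    "aa": (0.18, 0.066),
    "snar": (0.012, 0.005),
}

DEFAULT_STUDY_TYPE_PROBS = {"LLNA": 0.40, "GPMT": 0.30,
                            "Buehler": 0.20, "PatchTest": 0.10}


def expected_within_similarity(flip_rate: float, density: float,
                               bits: int = 256) -> float:
    """Closed-form expected Tanimoto between two independent corruptions of
    the same prototype fingerprint.

    Each prototype bit is set with probability ``density``; each copy flips
    each bit independently with probability ``flip_rate``. Per bit,
    P(both set) = d(1-f)^2 + (1-d)f^2 and P(both unset) = d f^2 +
    (1-d)(1-f)^2; the expectation of the ratio is approximated by the ratio
    of expectations, exact in the many-bit limit (``bits`` is accepted for
    signature symmetry with the generator; the approximation ignores
    finite-size fluctuations).
    """
    if not 0.0 <= flip_rate <= 1.0 or not 0.0 <= density <= 1.0:
        raise ValueError("flip_rate and density must lie in [0, 1]")
    f, d = flip_rate, density
    p11 = d * (1 - f) ** 2 + (1 - d) * f ** 2
    p_mismatch = 2 * f * (1 - f)  # bit set in exactly one copy
    denom = p11 + p_mismatch
    return p11 / denom if denom > 0 else 0.0


def flip_rate_for_similarity(target: float, density: float,
                             bits: int = 256) -> float:
    """Bit-flip rate whose expected within-cluster Tanimoto equals ``target``.

    Bisection on the closed form. The expectation is monotone decreasing in
    the flip rate only until flips start pushing the effective bit density
    toward 0.5 (for sparse prototypes, chance overlap grows again near
    f = 0.5), so the search is restricted to the decreasing branch.
    """
    if not 0.0 < target <= 1.0:
        raise ValueError("target similarity must lie in (0, 1]")
    import numpy as _np
    grid = _np.linspace(0.0, 0.5, 201)
    values = [expected_within_similarity(f, density, bits) for f in grid]
    lo, hi = 0.0, float(grid[int(_np.argmin(values))])
    if target <= min(values):
        return hi
    for _ in range(80):
        mid = (lo + hi) / 2
        if expected_within_similarity(mid, density, bits) > target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


@dataclass
class UniverseConfig:
    """Knobs of the synthetic chemical universe.

    Defaults describe the regime the analysis targets: a few thousand
    chemicals in ~10 structural clusters, within-cluster Tanimoto around
    0.9, a global sensitizer prevalence of 21% spread across clusters,
    alert flags enriched among sensitizers, lognormal molecular weight
    (median 250 Da), 1-2 studies per chemical and a 5% per-study chance of
    an outcome contradicting the true label.

    ``label_bits`` reserves a few fingerprint positions per cluster that are
    set for sensitizers and unset for non-sensitizers before per-bit noise,
    emulating the reactive substructures that make close structural
    neighbors share sensitization status (the premise of read-across); 0
    removes any fingerprint-label association beyond cluster membership.
    """

    n_chemicals: int = 2000
    n_clusters: int = 10
    n_bits: int = 256
    density: float = 0.30
    flip_rate: float | None = None          # None -> calibrated to target
    target_within_similarity: float = 0.90
    background_fraction: float = 0.10
    prevalence: float = 0.21
    prevalence_spread: float = 0.20          # cluster prevalences span
    per_cluster_prevalence: Sequence[float] | None = None
    alert_probs: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ALERT_PROBS))
    label_bits: int = 12                     # per-cluster label-informative bits
    mw_median: float = 250.0
    mw_sigma: float = 0.7
    mw_sensitizer_factor: float = 1.0        # >1 shifts sensitizer MW up
    studies_per_chemical: float = 1.8        # mean; at least one study each
    study_flip_prob: float = 0.05
    inconclusive_prob: float = 0.02
    study_type_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STUDY_TYPE_PROBS))
    nested_bits: int = 0                     # implication-chain bits (redundancy)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chemicals < self.n_clusters:
            raise ValueError("n_chemicals must be >= n_clusters")
        if self.n_clusters < 1 or self.n_bits < 8:
            raise ValueError("need >= 1 cluster and >= 8 fingerprint bits")
        probs = [self.density, self.background_fraction, self.prevalence,
                 self.study_flip_prob, self.inconclusive_prob]
        if self.flip_rate is not None:
            probs.append(self.flip_rate)
        if self.per_cluster_prevalence is not None:
            probs.extend(self.per_cluster_prevalence)
            if len(self.per_cluster_prevalence) != self.n_clusters:
                raise ValueError("per_cluster_prevalence length must equal "
                                 "n_clusters")
        probs.extend(p for pair in self.alert_probs.values() for p in pair)
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.nested_bits < 0 or self.nested_bits > self.n_bits // 2:
            raise ValueError("nested_bits must lie in [0, n_bits/2]")
        if self.label_bits < 0 or self.label_bits > self.n_bits // 4:
            raise ValueError("label_bits must lie in [0, n_bits/4]")

    def resolved_flip_rate(self) -> float:
        if self.flip_rate is not None:
            return self.flip_rate
        return flip_rate_for_similarity(self.target_within_similarity,
                                        self.density, self.n_bits)

    def cluster_prevalences(self) -> np.ndarray:
        """Cluster sensitizer prevalences: explicit list if given, otherwise
        an even spread symmetric around the global prevalence (so the
        expected global rate is exact)."""
        if self.per_cluster_prevalence is not None:
            return np.asarray(self.per_cluster_prevalence, dtype=float)
        k = self.n_clusters
        if k == 1:
            return np.array([self.prevalence])
        offsets = np.linspace(-0.5, 0.5, k) * self.prevalence_spread
        return np.clip(self.prevalence + offsets, 0.0, 1.0)


@dataclass
class UniverseTruth:
    """Ground truth withheld from the analysis path (for tests)."""

    cluster: dict[str, int]     # -1 for background chemicals
    label: dict[str, str]


def _draw_fingerprint(rng: np.random.Generator, prototype: np.ndarray,
                      flip_rate: float, nested_bits: int) -> frozenset[int]:
    flips = rng.random(prototype.size) < flip_rate
    vec = prototype ^ flips
    if nested_bits:
        # implication chain: bit i set forces bits < i set, emulating the
        # redundant counted substructure bits of real fingerprints
        top = np.nonzero(vec[:nested_bits])[0]
        if top.size:
            vec[:top.max() + 1] = True
    if not vec.any():
        vec[int(rng.integers(prototype.size))] = True  # no empty fingerprints
    return frozenset(np.nonzero(vec)[0].tolist())


def generate_universe(config: UniverseConfig
                      ) -> tuple[list[ChemicalRecord], list[StudyRecord],
                                 UniverseTruth]:
    """Generate a chemical universe, its study table, and the ground truth.

    Deterministic given ``config.seed``. Cluster members are per-bit
    corruptions of their cluster prototype; background chemicals get fresh
    random fingerprints. Labels are drawn per cluster prevalence; alert
    flags per class-conditional probabilities (RD recomputed as their OR);
    studies flip away from the true label with the per-assay error rate.
    """
    rng = np.random.default_rng(config.seed)
    flip_rate = config.resolved_flip_rate()
    prevalences = config.cluster_prevalences()

    n_background = int(round(config.background_fraction * config.n_chemicals))
    n_clustered = config.n_chemicals - n_background
    cluster_of = np.full(config.n_chemicals, -1, dtype=int)
    cluster_of[:n_clustered] = np.arange(n_clustered) % config.n_clusters

    prototypes = rng.random((config.n_clusters, config.n_bits)) < config.density
    if config.label_bits:
        # one dedicated label-bit block per cluster (plus one for background)
        label_positions = np.stack([
            rng.choice(config.n_bits, size=config.label_bits, replace=False)
            for _ in range(config.n_clusters + 1)])
    width = len(str(config.n_chemicals - 1))

    type_names = list(config.study_type_probs)
    type_p = np.array([config.study_type_probs[t] for t in type_names])
    type_p = type_p / type_p.sum()

    chemicals: list[ChemicalRecord] = []
    studies: list[StudyRecord] = []
    truth = UniverseTruth(cluster={}, label={})

    for i in range(config.n_chemicals):
        cid = f"C{i:0{width}d}"
        cluster = int(cluster_of[i])
        if cluster >= 0:
            proto = prototypes[cluster]
            p_sens = prevalences[cluster]
        else:
            proto = rng.random(config.n_bits) < config.density
            p_sens = config.prevalence
        label = SENSITIZER if rng.random() < p_sens else NON_SENSITIZER
        if config.label_bits:
            proto = proto.copy()
            proto[label_positions[cluster]] = label == SENSITIZER
        fingerprint = _draw_fingerprint(rng, proto, flip_rate, config.nested_bits)

        flags = {}
        for alert, (p_pos, p_neg) in config.alert_probs.items():
            flags[alert] = bool(rng.random() <
                                (p_pos if label == SENSITIZER else p_neg))
        alert_flags = AlertFlags(**flags).normalized()

        median = config.mw_median * (config.mw_sensitizer_factor
                                     if label == SENSITIZER else 1.0)
        mw = float(rng.lognormal(mean=np.log(median), sigma=config.mw_sigma))

        chemicals.append(ChemicalRecord(
            id=cid, fingerprint=fingerprint, mw=mw,
            alert_flags=alert_flags, label=label))
        truth.cluster[cid] = cluster
        truth.label[cid] = label

        n_studies = 1 + rng.poisson(max(config.studies_per_chemical - 1.0, 0.0))
        for _ in range(n_studies):
            stype = type_names[int(rng.choice(len(type_names), p=type_p))]
            if rng.random() < config.inconclusive_prob:
                outcome = OUTCOME_INCONCLUSIVE
            else:
                observed_sens = (label == SENSITIZER) ^ \
                    (rng.random() < config.study_flip_prob)
                outcome = OUTCOME_SENS if observed_sens else OUTCOME_NON
            studies.append(StudyRecord(
                chemical_id=cid, study_type=stype,
                study_kind="exp key skin sensitization",
                outcome=outcome,
                klimisch=int(rng.choice([1, 2, 3], p=[0.3, 0.6, 0.1])),
                year=int(rng.integers(1975, 2015)),
                has_results=bool(rng.random() < 0.97),
                has_methods=bool(rng.random() < 0.97)))

    return chemicals, studies, truth
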