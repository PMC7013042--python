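"""Synthetic cohort generator with planted rich-club organization.

Emulates the statistical structure of a three-group (NC / MCI / AD)
connectome study on a 246-node parcellation:

* **Structural side** — a planted-partition random graph.  The first
  ``n_hubs`` nodes are hubs; hub-hub, hub-nonhub and nonhub-nonhub pairs
  receive edges with probabilities ``p_rich``, ``p_feeder`` and ``p_local``,
  each thinned by a group-specific keep fraction (disease groups lose
  feeder and local connections preferentially).  Present edges carry
  streamline counts of at least 3 (shifted geometric), and regions carry
  log-normal surface areas, so the full count -> weight -> binary
  construction pipeline is exercised.
* **Functional side** — for structurally connected pairs the functional
  weight is a monotone squash of ``rho * z(SC) + sqrt(1 - rho^2) * noise``
  where ``z`` is the same rank-based Gaussianization the coupling estimator
  uses, making the group-specific coupling strength ``rho`` a recoverable
  parameter.  A configurable fraction of connected-pair draws is zeroed,
  mimicking the zeroing of negative correlations; unconnected pairs get
  low-magnitude background connectivity.
* **Clinical side** — age, sex, education and five clinical scores drawn
  per group, with score means tied to each subject's feeder density and
  coupling through linear loadings (centered so group means stay at their
  configured targets in expectation).

One global integer seed drives everything; each subject gets an independent
substream derived by hashing ``(seed, subject_id)``, so cohorts are
reproducible and independent of generation order.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.stats import norm

from .construct import sc_from_streamlines
from .containers import (
    GROUPS,
    CohortTable,
    FunctionalNetwork,
    StreamlineCountMatrix,
    StructuralNetwork,
    SubjectRecord,
    ValidationError,
)
from .coupling import gaussianize, sc_fc_coupling
from .richclub import HubSet, classify_edges

__all__ = [
    "GeneratorConfig",
    "generate_structural_connectome",
    "generate_functional_connectome",
    "generate_covariates_and_scores",
    "generate_subject",
    "generate_cohort",
    "generate_structural_cohort",
    "planted_hub_set",
]


def _default_degradation() -> dict:
    # keep fractions (feeder, local, rich): disease groups lose feeder and
    # local edges preferentially, rich-club edges are comparatively spared
    return {
        "NC": {"feeder_keep": 1.0, "local_keep": 1.0, "rich_keep": 1.0},
        "MCI": {"feeder_keep": 0.90, "local_keep": 0.90, "rich_keep": 0.97},
        "AD": {"feeder_keep": 0.85, "local_keep": 0.85, "rich_keep": 0.95},
    }


def _default_coupling() -> dict:
    # structure-function coupling rises with disease stage
    return {"NC": 0.30, "MCI": 0.40, "AD": 0.50}


def _default_covariate_model() -> dict:
    return {
        "NC": {"age_mean": 75.1, "age_sd": 9.863, "edu_mean": 17.0, "edu_sd": 2.466,
               "female_prop": 19 / 38},
        "MCI": {"age_mean": 75.3, "age_sd": 6.957, "edu_mean": 15.6, "edu_sd": 3.162,
                "female_prop": 20 / 40},
        "AD": {"age_mean": 74.6, "age_sd": 10.025, "edu_mean": 15.4, "edu_sd": 2.179,
               "female_prop": 8 / 19},
    }


def _default_score_model() -> dict:
    # group means / SDs per clinical scale, plus linear loadings on the
    # subject's feeder connection density and SC-FC coupling (centered at
    # their per-group expectations so the means are preserved)
    return {
        "CDR": {"means": {"NC": 0.03, "MCI": 0.49, "AD": 1.00},
                "sds": {"NC": 0.123, "MCI": 0.443, "AD": 0.480},
                "b_feeder": -300.0, "b_coupling": 2.0},
        "FAQ": {"means": {"NC": 0.08, "MCI": 3.10, "AD": 15.06},
                "sds": {"NC": 0.370, "MCI": 4.870, "AD": 8.892},
                "b_feeder": -4000.0, "b_coupling": 30.0},
        "MMSE": {"means": {"NC": 29.24, "MCI": 27.90, "AD": 21.53},
                 "sds": {"NC": 1.048, "MCI": 1.834, "AD": 4.708},
                 "b_feeder": 800.0, "b_coupling": -6.0},
        "MoCA": {"means": {"NC": 25.00, "MCI": 20.05, "AD": 13.87},
                 "sds": {"NC": 2.404, "MCI": 5.755, "AD": 5.885},
                 "b_feeder": 2000.0, "b_coupling": -15.0},
        "GDS": {"means": {"NC": 0.50, "MCI": 1.83, "AD": 1.84},
                "sds": {"NC": 0.740, "MCI": 1.581, "AD": 1.395},
                "b_feeder": 0.0, "b_coupling": 0.0},
    }


@dataclass
class GeneratorConfig:
    """All tunable knobs of the synthetic cohort, with study-scale defaults.

    Edge probabilities are calibrated so that a control-subject network has
    ~3.1% density, hub mean degree ~12.6, and class proportions of roughly
    11.5% rich-club / 34.4% feeder / 54.1% local edges.
    """

    n_nodes: int = 246
    n_cortical: int = 210
    n_subcortical: int = 36
    n_hubs: int = 43
    group_sizes: dict = field(default_factory=lambda: {"NC": 38, "MCI": 40, "AD": 19})
    p_rich: float = 0.120
    p_feeder: float = 0.0372
    p_local: float = 0.0249
    degradation: dict = field(default_factory=_default_degradation)
    coupling_strength: dict = field(default_factory=_default_coupling)
    fc_noise_sd: float = 1.0
    fc_background_sd: float = 0.15
    fc_zero_frac: float = 0.10
    fc_squash_scale: float = 3.0  # Phi(latent / scale); larger = more linear
    rich_nesting: float = 0.5     # hub-block nesting scale (fraction of n_hubs); 0 = flat
    count_geom_p: float = 0.2     # present-edge counts: 3 + Geometric(p) - 1
    area_log_mean: float = math.log(800.0)  # region surface areas, mm^2
    area_log_sd: float = 0.4
    score_model: dict = field(default_factory=_default_score_model)
    covariate_model: dict = field(default_factory=_default_covariate_model)
    coupling_min_edges: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0 < self.n_hubs < self.n_nodes:
            raise ValidationError("need 0 < n_hubs < n_nodes")
        if self.n_cortical + self.n_subcortical != self.n_nodes:
            raise ValidationError("n_cortical + n_subcortical must equal n_nodes")
        for name in ("p_rich", "p_feeder", "p_local", "fc_zero_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        for g, n in self.group_sizes.items():
            if g not in GROUPS:
                raise ValidationError(f"unknown group {g!r}")
            if n < 1:
                raise ValidationError(f"group {g} size must be >= 1")
        for g, d in self.degradation.items():
            for key in ("feeder_keep", "local_keep", "rich_keep"):
                if not 0.0 <= d[key] <= 1.0:
                    raise ValidationError(f"{g}.{key} must be in [0, 1]")
        for g, rho in self.coupling_strength.items():
            if not -1.0 < rho < 1.0:
                raise ValidationError(f"coupling_strength[{g}] must be in (-1, 1)")
        if self.fc_noise_sd <= 0 or self.fc_background_sd <= 0:
            raise ValidationError("noise SDs must be positive")
        if not 0 < self.count_geom_p <= 1:
            raise ValidationError("count_geom_p must be in (0, 1]")
        if self.rich_nesting < 0:
            raise ValidationError("rich_nesting must be >= 0")

    # ------------------------------------------------------------------
    # analytic expectations used for score centering and tests
    def node_labels(self) -> list[str]:
        return [f"R{i:03d}" for i in range(self.n_nodes)]

    def hub_labels(self) -> list[str]:
        return self.node_labels()[: self.n_hubs]

    def pair_counts(self) -> dict[str, int]:
        h, n = self.n_hubs, self.n_nodes
        return {
            "rich_club": h * (h - 1) // 2,
            "feeder": h * (n - h),
            "local": (n - h) * (n - h - 1) // 2,
        }

    def expected_class_density(self, group: str) -> dict[str, float]:
        """Expected edge-class densities (all-pairs denominator) per group."""
        d = self.degradation[group]
        pairs = self.pair_counts()
        total = self.n_nodes * (self.n_nodes - 1) // 2
        p = {
            "rich_club": self.p_rich * d["rich_keep"],
            "feeder": self.p_feeder * d["feeder_keep"],
            "local": self.p_local * d["local_keep"],
        }
        return {c: p[c] * pairs[c] / total for c in p}

    def squash_attenuation(self) -> float:
        """Pearson attenuation factor of the CDF squash.

        For a unit-variance latent L and FC = Phi(L / c), the correlation
        of any Gaussian variable with FC shrinks by
        ``sqrt(u / arcsin(u))`` with ``u = 1 / (1 + c^2)`` — about 0.999
        at the default scale, so recovered coupling sits essentially on
        the generative rho.
        """
        u = 1.0 / (1.0 + self.fc_squash_scale**2)
        return math.sqrt(u / math.asin(u))

    def expected_coupling(self, group: str) -> float:
        """Expected recovered coupling: rho attenuated by the squash."""
        return self.coupling_strength[group] * self.squash_attenuation()

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        base = cls().to_dict()
        unknown = set(d) - set(base)
        if unknown:
            raise ValidationError(f"unknown generator config keys: {sorted(unknown)}")
        merged = {**base, **d}
        # nested dicts merge shallowly per group / score
        for key in ("degradation", "covariate_model", "score_model"):
            if key in d:
                merged[key] = {**base[key], **d[key]}
        return cls(**merged)


def planted_hub_set(config: GeneratorConfig) -> HubSet:
    """The ground-truth hub set (the first ``n_hubs`` node indices)."""
    return HubSet(
        hub_labels=config.hub_labels(),
        selection_rule={"mode": "planted", "n_hubs": config.n_hubs},
    )


def subject_rng(seed: int, subject_id: str) -> np.random.Generator:
    """Independent per-subject substream from a stable hash of the id."""
    digest = hashlib.sha256(subject_id.encode()).digest()
    key = int.from_bytes(digest[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, key]))


def _nested_hub_probs(h: int, p_rich: float, tau: float) -> np.ndarray:
    """Hub-block edge probabilities with a nested (core-weighted) profile.

    Pair (i, j) of hub ranks gets probability ``min(1, A * exp(-(i+j)/tau))``
    with ``A`` solved by bisection so the block-average equals ``p_rich``.
    Low-rank (core) hub pairs are densest, mirroring the empirically nested
    structure of rich clubs; with ``tau -> inf`` the block is flat.
    """
    i, j = np.triu_indices(h, k=1)
    if tau <= 0 or not np.isfinite(tau):
        w = np.ones(len(i))
    else:
        w = np.exp(-(i + j) / tau)
    if p_rich <= 0:
        return np.zeros((h, h))
    if p_rich >= 1.0:
        block = np.ones((h, h))
        np.fill_diagonal(block, 0.0)
        return block
    lo, hi = 0.0, 1.0
    while np.minimum(1.0, hi * w).mean() < p_rich:
        hi *= 2.0
        if hi > 1e12:
            break
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if np.minimum(1.0, mid * w).mean() < p_rich:
            lo = mid
        else:
            hi = mid
    p = np.minimum(1.0, hi * w)
    block = np.zeros((h, h))
    block[i, j] = p
    block[j, i] = p
    return block


def generate_structural_connectome(
    config: GeneratorConfig, group: str, rng: np.random.Generator
) -> StreamlineCountMatrix:
    """Sample one subject's streamline-count matrix with a planted rich club.

    Hub-hub, hub-nonhub and nonhub-nonhub pairs receive edges independently
    with probability ``p_class * keep_frac(group)``; the hub block is
    nested (average probability ``p_rich``, core pairs denser) so the club
    stays denser than its degree-preserving null across the whole hub
    degree range.  Present edges carry counts ``3 + Geometric(count_geom_p)
    - 1`` (support starting at the minimum streamline threshold of 3).
    """
    if group not in config.degradation:
        raise ValidationError(f"group {group!r} not in degradation map")
    n, h = config.n_nodes, config.n_hubs
    d = config.degradation[group]
    is_hub = np.zeros(n, dtype=bool)
    is_hub[:h] = True
    hub_count = is_hub[:, None].astype(int) + is_hub[None, :].astype(int)
    prob = np.empty((n, n))
    tau = config.rich_nesting * h if config.rich_nesting > 0 else np.inf
    prob[hub_count == 2] = (
        _nested_hub_probs(h, config.p_rich, tau) * d["rich_keep"]
    )[np.ones((h, h), dtype=bool)]
    prob[hub_count == 1] = config.p_feeder * d["feeder_keep"]
    prob[hub_count == 0] = config.p_local * d["local_keep"]

    iu, ju = np.triu_indices(n, k=1)
    present = rng.random(len(iu)) < prob[iu, ju]
    counts = np.zeros((n, n), dtype=np.int64)
    n_edges = int(present.sum())
    if n_edges:
        vals = 3 + rng.geometric(config.count_geom_p, size=n_edges) - 1
        counts[iu[present], ju[present]] = vals
        counts[ju[present], iu[present]] = vals
    areas = rng.lognormal(config.area_log_mean, config.area_log_sd, size=n)
    return StreamlineCountMatrix(counts=counts, surface_areas=areas,
                                 labels=config.node_labels())


def generate_functional_connectome(
    sc: StructuralNetwork,
    rho: float,
    fc_noise_sd: float = 1.0,
    rng: np.random.Generator | None = None,
    background_sd: float = 0.15,
    zero_frac: float = 0.10,
    squash_scale: float = 3.0,
) -> FunctionalNetwork:
    """Sample a functional network whose coupling to ``sc`` is ``rho``.

    Connected pairs: ``FC = Phi((rho * z(SC) + sqrt(1 - rho^2) * eps) /
    squash_scale)`` with ``z`` the Blom inverse-normal scores of the SC
    weights, ``eps`` Gaussian noise and ``Phi`` the standard normal CDF — a
    monotone squash into (0, 1), near-linear over the latent's bulk at the
    default scale so the Pearson coupling stays essentially ``rho``.  A
    ``zero_frac`` share of connected-pair draws is set to zero, standing in
    for negative correlations zeroed at construction.  Unconnected pairs
    receive ``min(|N(0, background_sd)|, 1)``.
    """
    if not -1.0 < rho < 1.0:
        raise ValueError("|rho| must be < 1")
    rng = rng if rng is not None else np.random.default_rng()
    n = sc.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    connected = sc.weights[iu, ju] > 0
    n_conn = int(connected.sum())
    if n_conn == 0:
        raise ValueError("structural network has no edges; coupling undefined")
    if n_conn < 3:
        raise ValueError("need at least 3 structural edges to generate FC")
    z = gaussianize(sc.weights[iu[connected], ju[connected]])
    eps = rng.normal(0.0, fc_noise_sd, size=n_conn)
    latent = rho * z + math.sqrt(1.0 - rho**2) * eps
    fc_conn = norm.cdf(latent / squash_scale)
    zeroed = rng.random(n_conn) < zero_frac
    fc_conn[zeroed] = 0.0

    vals = np.minimum(np.abs(rng.normal(0.0, background_sd, size=len(iu))), 1.0)
    vals[connected] = fc_conn
    weights = np.zeros((n, n))
    weights[iu, ju] = vals
    weights[ju, iu] = vals
    return FunctionalNetwork(weights=weights, labels=list(sc.labels))


def generate_covariates_and_scores(
    config: GeneratorConfig,
    group: str,
    structural_summaries: dict,
    rng: np.random.Generator,
) -> tuple[float, str, float, dict[str, float]]:
    """Draw (age, sex, education, clinical scores) for one subject.

    Scores follow ``group mean + b_feeder * (feeder_density - E[density])
    + b_coupling * (coupling - E[coupling]) + Gaussian noise``; the
    centering keeps group means at their configured targets in expectation.
    """
    cm = config.covariate_model[group]
    age = float(rng.normal(cm["age_mean"], cm["age_sd"]))
    education = float(rng.normal(cm["edu_mean"], cm["edu_sd"]))
    sex = "F" if rng.random() < cm["female_prop"] else "M"

    fd = structural_summaries["feeder_density"]
    cp = structural_summaries["coupling"]
    fd_c = fd - config.expected_class_density(group)["feeder"]
    cp_c = (cp - config.expected_coupling(group)) if np.isfinite(cp) else 0.0
    scores = {}
    for name, sm in config.score_model.items():
        mu = sm["means"][group] + sm["b_feeder"] * fd_c + sm["b_coupling"] * cp_c
        sd = sm["sds"][group]
        scores[name] = float(mu + (rng.normal(0.0, sd) if sd > 0 else 0.0))
    return age, sex, education, scores


def generate_subject(
    config: GeneratorConfig, group: str, subject_id: str
) -> SubjectRecord:
    """Generate one complete subject from its dedicated RNG substream."""
    rng = subject_rng(config.seed, subject_id)
    m = generate_structural_connectome(config, group, rng)
    sc = sc_from_streamlines(m)
    fc = generate_functional_connectome(
        sc,
        rho=config.coupling_strength[group],
        fc_noise_sd=config.fc_noise_sd,
        rng=rng,
        background_sd=config.fc_background_sd,
        zero_frac=config.fc_zero_frac,
        squash_scale=config.fc_squash_scale,
    )
    hubs = planted_hub_set(config)
    feeder_density = classify_edges(sc, hubs).densities["feeder"]
    try:
        cp = sc_fc_coupling(sc, fc, scope="all", min_edges=config.coupling_min_edges,
                            subject_id=subject_id).r
    except ValueError:
        cp = float("nan")
    age, sex, education, scores = generate_covariates_and_scores(
        config, group, {"feeder_density": feeder_density, "coupling": cp}, rng
    )
    return SubjectRecord(
        subject_id=subject_id,
        group=group,
        sc_counts=m,
        sc=sc,
        fc=fc,
        age=age,
        sex=sex,
        education=education,
        scores=scores,
    )


def _subject_ids(config: GeneratorConfig) -> list[tuple[str, str]]:
    out = []
    for group in GROUPS:
        if group not in config.group_sizes:
            continue
        for i in range(config.group_sizes[group]):
            out.append((group, f"{group}_{i + 1:03d}"))
    return out


def generate_cohort(config: GeneratorConfig) -> CohortTable:
    """Generate the full cohort; deterministic given ``config.seed``."""
    subjects = [generate_subject(config, g, sid) for g, sid in _subject_ids(config)]
    return CohortTable(
        subjects=subjects,
        provenance={
            "generator_config": config.to_dict(),
            "planted_hubs": config.hub_labels(),
        },
    )


def generate_structural_cohort(
    config: GeneratorConfig,
) -> list[tuple[str, str, StructuralNetwork]]:
    """Structural networks only (group, subject_id, network); fast path for
    simulations that never touch the functional or clinical side."""
    out = []
    for group, sid in _subject_ids(config):
        rng = subject_rng(config.seed, sid)
        m = generate_structural_connectome(config, group, rng)
        out.append((group, sid, sc_from_streamlines(m)))
    return out
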