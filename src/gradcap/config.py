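"""Configuration dataclasses for every pipeline stage.

A :class:`StudyConfig` is fully serializable (YAML/JSON); its SHA-256 hash is
stamped into every output table so results are traceable to the exact
configuration that produced them.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml


@dataclass
class PreprocessConfig:
    """Temporal preprocessing settings.

    The band-pass is implemented as a projection that removes out-of-band
    sine/cosine components evaluated on the retained frames only, so the
    whole preprocessing chain is idempotent (re-running it is a no-op).
    """

    n_initial_drop: int = 2
    fd_threshold_mm: float = 0.4
    band_low_hz: float = 0.01
    band_high_hz: float = 0.1
    filter_family: str = "spectral_projection"

    def validate(self, dt_seconds: float) -> None:
        nyquist = 0.5 / dt_seconds
        if not (0.0 < self.band_low_hz < self.band_high_hz < nyquist):
            raise ValueError(
                f"band [{self.band_low_hz}, {self.band_high_hz}] Hz must satisfy "
                f"0 < low < high < Nyquist ({nyquist:g} Hz)"
            )


@dataclass
class GradientConfig:
    """Diffusion-map embedding settings.

    ``sparsity`` keeps the top ``1 - sparsity`` fraction of weighted
    connections per row; ``alpha`` controls density normalization of the
    affinity kernel; ``diffusion_time`` 0 selects automated damping
    (components scaled by lambda / (1 - lambda)).
    """

    sparsity: float = 0.90
    alpha: float = 0.5
    diffusion_time: float = 0.0
    n_components: int = 10
    #: Alignment target: "model_template" embeds the generative model's
    #: noise-free baseline covariance (the synthetic stand-in for an
    #: external large-sample template); "cohort_baseline" builds an
    #: iterative mean template from the cohort's own baseline gradients.
    reference_source: str = "model_template"

    def validate(self) -> None:
        if not (0.0 < self.sparsity < 1.0):
            raise ValueError("sparsity must lie in (0, 1)")
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must lie in [0, 1]")
        if self.diffusion_time < 0:
            raise ValueError("diffusion_time must be >= 0")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")


@dataclass
class CapConfig:
    """Co-activation-pattern settings."""

    k: int = 8
    n_init: int = 10
    #: Occurrence-rate denominator: "retained" frames after censoring or all
    #: "acquired" frames of the scan.
    denominator: str = "retained"
    #: Where labelling centroids come from: k-means on the cohort's own
    #: frames ("kmeans") or the generator's state topographies
    #: ("ground_truth"), mirroring a supervised template set.
    centroids_source: str = "ground_truth"
    #: Cap on stacked frames fed to k-means (subsampled deterministically).
    max_kmeans_frames: int = 6000


@dataclass
class ClusterConfig:
    """Monte-Carlo cluster-extent threshold settings."""

    voxel_p: float = 0.01
    fwe_p: float = 0.05
    n_iterations: int = 1000
    smoothness_fwhm: float = 1.5  # in voxel units of the node lattice


@dataclass
class StatsConfig:
    """Inference settings; Bonferroni family sizes are fixed per analysis."""

    alpha: float = 0.05
    family_networks: int = 7
    family_caps: int = 8
    family_brain_behavior_gradients: int = 7
    family_brain_behavior_caps: int = 3
    cluster: ClusterConfig = field(default_factory=ClusterConfig)


@dataclass
class EffectConfig:
    """Planted condition effects for the synthetic cohort.

    Defaults emulate the study conditions: a contraction of the FPN and SMN
    hierarchy positions toward the gradient centre, a raised global signal
    under drug, a shift of state occupancy from FPN+/SMN+ toward GN+, and
    questionnaire totals coupled (negatively) to realized differentiation.
    """

    #: Hierarchy contraction applied to FPN and SMN (toward 0.5), in
    #: hierarchy units (adjacent networks are 1/6 apart).
    gradient_shift: float = 0.20
    #: Additional amplitude of the shared global signal under drug.
    global_coupling_increase: float = 0.4
    #: Occupancy changes for FPN+, SMN+, GN+ (others renormalized implicitly
    #: through the target distributions in the generator).
    occupancy_shift_fpn: float = -0.12
    occupancy_shift_smn: float = -0.12
    occupancy_shift_gn: float = 0.24
    #: Coupling of the questionnaire total to the realized per-subject
    #: contraction (points of total per hierarchy-unit of contraction).
    asc_gain: float = 150.0
    #: SD of the per-subject multiplicative effect-size jitter.
    subject_sd: float = 0.25
    #: Number of subjects with missing questionnaires.
    n_missing_asc: int = 3

    def null(self) -> "EffectConfig":
        """Copy with every planted effect set to zero (null cohort)."""
        return dataclasses.replace(
            self, gradient_shift=0.0, global_coupling_increase=0.0,
            occupancy_shift_fpn=0.0, occupancy_shift_smn=0.0,
            occupancy_shift_gn=0.0, asc_gain=0.0,
        )


@dataclass
class CohortConfig:
    """Synthetic cohort dimensions and signal amplitudes."""

    n_subjects: int = 16
    n_nodes: int = 350
    n_frames: int = 180
    dt_seconds: float = 2.0
    cap_amp: float = 0.8
    latent_amp: float = 1.6
    global_amp: float = 0.2
    noise_sd: float = 1.0
    #: Markov-chain self-transition weight (state persistence).
    persistence: float = 0.7
    #: Motion model: per-frame derivative SD and spike settings.
    motion_base_sd: float = 0.02
    motion_spike_prob: float = 0.03
    motion_spike_mm: float = 0.5


@dataclass
class StudyConfig:
    """Master configuration for an end-to-end study."""

    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    effects: EffectConfig = field(default_factory=EffectConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    gradient: GradientConfig = field(default_factory=GradientConfig)
    cap: CapConfig = field(default_factory=CapConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        def build(klass, sub):
            fields = {f.name for f in dataclasses.fields(klass)}
            unknown = set(sub) - fields
            if unknown:
                raise ValueError(f"unknown {klass.__name__} keys: {sorted(unknown)}")
            return klass(**sub)

        kwargs: dict = {}
        if "seed" in d:
            kwargs["seed"] = int(d["seed"])
        for key, klass in (
            ("cohort", CohortConfig), ("effects", EffectConfig),
            ("preprocess", PreprocessConfig), ("gradient", GradientConfig),
            ("cap", CapConfig),
        ):
            if key in d:
                kwargs[key] = build(klass, d[key])
        if "stats" in d:
            sub = dict(d["stats"])
            cluster = sub.pop("cluster", None)
            stats = build(StatsConfig, sub)
            if cluster is not None:
                stats.cluster = build(ClusterConfig, cluster)
            kwargs["stats"] = stats
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
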