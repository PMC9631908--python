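"""Pipeline configuration: every numeric choice in one validated object."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import yaml

__all__ = ["PipelineConfig", "load_config", "dump_config"]

CONFIG_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class PipelineConfig:
    """All thresholds, seeds and paths used by the study pipeline.

    Defaults are the protocol's standard values: mean-Tc removal below
    0.2, |r| > 0.7 activity/cross-correlation thresholds, an 80/20
    train/test split, ESD outlier test at α = 0.05 and an r²–q² closing
    gap of 0.2.
    """

    schema_version: int = CONFIG_SCHEMA_VERSION
    # inputs/outputs
    compound_csv: str | None = None
    descriptor_csv: str | None = None
    score_csv: str | None = None
    output_dir: str = "results"
    targets: tuple[str, ...] = ("dat",)
    # curation
    tc_removal_threshold: float = 0.2
    train_fraction: float = 0.8
    # fingerprints
    fingerprint_bits: int = 1024
    fingerprint_max_path: int = 7
    # descriptors
    descriptor_names: tuple[str, ...] = (
        "b_max1len", "fasa_h", "opr_leadlike", "peoe_vsa_neg0",
        "peoe_vsa_pos3", "q_vsa_fpneg", "a_don", "e_tor",
    )
    peoe_iterations: int = 6
    # model building
    activity_correlation_threshold: float = 0.7
    cross_correlation_threshold: float = 0.7
    gap_tol: float = 0.2
    r2_slack: float = 0.02
    esd_alpha: float = 0.05
    # consensus
    higher_better: dict = field(default_factory=dict)
    n_permutations: int = 100_000
    # randomness
    seed: int = 0

    def __post_init__(self):
        checks = [
            ("tc_removal_threshold", 0.0, 1.0),
            ("train_fraction", 0.5, 0.95),
            ("activity_correlation_threshold", 0.0, 1.0),
            ("cross_correlation_threshold", 0.0, 1.0),
            ("gap_tol", 0.0, 1.0),
            ("r2_slack", 0.0, 1.0),
            ("esd_alpha", 0.0, 0.5),
        ]
        for name, lo, hi in checks:
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        bad = [t for t in self.targets if t not in ("dat", "net", "sert")]
        if bad:
            raise ValueError(f"unknown transporter target(s): {bad}")
        if self.n_permutations < 10_000:
            raise ValueError("n_permutations must be at least 10000")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["targets"] = list(self.targets)
        d["descriptor_names"] = list(self.descriptor_names)
        return d


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    version = raw.pop("schema_version", CONFIG_SCHEMA_VERSION)
    if version != CONFIG_SCHEMA_VERSION:
        raise ValueError(f"unsupported config schema version {version}")
    for key in ("targets", "descriptor_names"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return PipelineConfig(schema_version=version, **raw)


def dump_config(cfg: PipelineConfig, path=None) -> str:
    text = yaml.safe_dump(cfg.to_dict(), sort_keys=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
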