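"""Synthetic assay datasets with the exact structure the model assumes.

Each labeled sample (P/LP, B/LB, reference, synonymous) is drawn from the
shared pair of skew-normal components with its own mixing weight: an
observation in sample ``i`` comes from the abnormal component with
probability ``w_i`` and from the normal component otherwise.  Because the
reference sample is itself a pathogenic/benign mixture, a target prior
probability of pathogenicity can be imposed by inverting the prior
identity: ``w_G = prior * w_P + (1 - prior) * w_B``.

The default configuration is the regime the calibration is designed for —
a well-separated assay (components at -3 and 0, unit scale, mild skew),
clinical control weights w_P = 0.9 and w_B = 0.05, a synonymous sample
that is almost purely normal (w_S = 0.02), a reference sample implying a
prior of 0.1, and 2000 variants per sample.

A truth sidecar (JSON) records the component indicator of every variant,
the true weights and the implied prior; it is written separately from the
score table so the fitting pipeline cannot accidentally consume it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .dataio import BLB, PLP, REF, SYN, AssayDataset, VariantRecord
from .distributions import SkewNormalParams, sn_sample

__all__ = ["GeneratorConfig", "generate", "make_fixture_suite", "write_truth", "read_truth"]

_LABEL_FOR_SAMPLE = {"P": PLP, "B": BLB, "G": REF, "S": SYN}


@dataclass(frozen=True)
class GeneratorConfig:
    theta_abnormal: SkewNormalParams = SkewNormalParams(-3.0, 1.0, 0.2)
    theta_normal: SkewNormalParams = SkewNormalParams(0.0, 1.0, -0.2)
    weights: dict = field(
        default_factory=lambda: {"P": 0.9, "B": 0.05, "S": 0.02}
    )
    sizes: dict = field(
        default_factory=lambda: {"P": 2000, "B": 2000, "G": 2000, "S": 2000}
    )
    seed: int = 0
    target_prior: float | None = 0.1

    def resolved_weights(self) -> dict[str, float]:
        """Weights with w_G filled in from the target prior when requested."""
        w = dict(self.weights)
        if self.target_prior is not None:
            w["G"] = self.target_prior * w["P"] + (1.0 - self.target_prior) * w["B"]
        if "G" not in w:
            raise ValueError("either weights['G'] or target_prior must be given")
        return w

    def __post_init__(self) -> None:
        w = self.resolved_weights()
        for key, value in w.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"weight for sample {key!r} must lie in [0, 1], got {value}")
        if not w["P"] > w["B"]:
            raise ValueError(
                "assay validity requires w_P > w_B (pathogenic variants more "
                f"likely functionally abnormal); got {w['P']} <= {w['B']}"
            )
        if self.target_prior is not None and not w["B"] <= w["G"] <= w["P"]:
            raise ValueError("target prior puts w_G outside [w_B, w_P]")
        for key, n in self.sizes.items():
            if n < 1:
                raise ValueError(f"sample size for {key!r} must be positive, got {n}")

    @property
    def true_prior(self) -> float:
        w = self.resolved_weights()
        return (w["G"] - w["B"]) / (w["P"] - w["B"])


def generate(config: GeneratorConfig) -> tuple[AssayDataset, dict]:
    """Draw a labeled dataset and its truth sidecar.

    Returns ``(dataset, truth)`` where ``truth`` holds the per-variant
    component indicators (1 = abnormal), the configured weights and the
    implied prior.  Deterministic in ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    weights = config.resolved_weights()
    records: list[VariantRecord] = []
    indicators: dict[str, list[int]] = {}
    for key in ("P", "B", "G", "S"):
        if key not in config.sizes or config.sizes[key] == 0:
            continue
        n = config.sizes[key]
        w = weights[key]
        from_abnormal = rng.random(n) < w
        scores = np.where(
            from_abnormal,
            sn_sample(config.theta_abnormal, n, rng),
            sn_sample(config.theta_normal, n, rng),
        )
        indicators[key] = from_abnormal.astype(int).tolist()
        for j in range(n):
            records.append(
                VariantRecord(
                    variant_id=f"{key.lower()}{j:05d}",
                    scores=(float(scores[j]),),
                    label=_LABEL_FOR_SAMPLE[key],
                )
            )
    dataset = AssayDataset(
        records=records,
        direction="low_scores_abnormal",
        metadata={"generator_seed": config.seed},
    )
    truth = {
        "seed": config.seed,
        "weights": weights,
        "prior": config.true_prior,
        "theta_abnormal": config.theta_abnormal.as_tuple(),
        "theta_normal": config.theta_normal.as_tuple(),
        "component_abnormal": indicators,
    }
    return dataset, truth


def make_fixture_suite(seed: int = 0) -> dict[str, GeneratorConfig]:
    """Canonical generator configurations covering the assay regimes.

    - ``well_separated``: the default configuration; both evidence
      directions reachable.
    - ``overlapping_pathogenic``: an assay blind to part of the disease
      mechanism — half of the pathogenic variants score like synonymous
      ones (w_P = 0.5), so benign evidence should not be assigned.
    - ``tiny_blb``: only 8 B/LB controls (lipid-phosphatase-assay-like
      sample sizes), stressing small-sample uncertainty.
    - ``no_synonymous``: the three-sample case; many assays report no
      synonymous variants.
    """
    return {
        "well_separated": GeneratorConfig(seed=seed),
        "overlapping_pathogenic": GeneratorConfig(
            weights={"P": 0.4, "B": 0.02, "S": 0.02},
            target_prior=0.05,
            seed=seed + 1,
        ),
        "tiny_blb": GeneratorConfig(
            sizes={"P": 205, "B": 8, "G": 267},
            weights={"P": 0.9, "B": 0.05},
            target_prior=0.1,
            seed=seed + 2,
        ),
        "no_synonymous": GeneratorConfig(
            sizes={"P": 2000, "B": 2000, "G": 2000},
            seed=seed + 3,
        ),
    }


def write_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1)


def read_truth(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
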