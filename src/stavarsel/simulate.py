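"""Synthetic OpenArray-like Ct datasets with known ground truth.

The generator emulates the structure of a serum small-extracellular-vesicle
miRNA screen: ~112 assays x ~78 samples in three cohorts (control, GORD,
cancer), a block of stable housekeeping assays and two constant spike-ins,
a handful of assays with planted cancer-vs-rest Ct shifts, per-sample
global Ct offsets (pre-analytic variation in input and extraction, which
makes raw expression non-comparable across samples), per-measurement
Gaussian Ct noise, and Ct-dependent non-amplification dropout.

Ct for assay a in sample s:

    Ct(a, s) = baseline(a) + offset(s) + effect(a) * is_cancer(s) + noise

A measurement goes missing with probability
``logistic((Ct - dropout_ct50) / dropout_scale)``, and any Ct at or past
the 40-cycle instrument limit is censored to missing. Effects are planted
in Ct space because the downstream transform is exponential: a shift of
``effect_ct`` cycles is a fold change of ``2**(-effect_ct)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .ct import CtMatrix

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_ct_dataset",
    "generate_null_dataset",
    "write_dataset",
]

CYCLE_LIMIT = 40.0


@dataclass
class SimulationConfig:
    """Generative parameters; defaults mirror the study's cohort layout."""

    n_control: int = 19
    n_gord: int = 20
    n_cancer: int = 39
    n_assays: int = 112
    n_hkg: int = 15
    n_spikein: int = 2
    n_informative: int = 5
    effect_ct: float = 1.5  # cycles; fold change 2**effect_ct between classes
    sample_offset_sd: float = 0.5  # cycles; pre-analytic global variation
    noise_sd: float = 1.0  # cycles; per-measurement noise, target assays
    hkg_noise_sd: float = 0.3  # cycles; housekeeping/spike-in assays are stable
    dropout_ct50: float | None = 38.0  # Ct of 50% amplification failure
    dropout_scale: float = 1.0  # cycles; logistic steepness
    target_baseline: tuple[float, float] = (24.0, 34.0)
    hkg_baseline: tuple[float, float] = (22.0, 28.0)
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("n_control", "n_gord", "n_cancer", "n_assays", "n_hkg", "n_spikein"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_informative < 0:
            raise ValueError("n_informative must be non-negative")
        if self.n_informative > self.n_assays - self.n_hkg - self.n_spikein:
            raise ValueError(
                "n_informative cannot exceed the number of non-housekeeping, "
                "non-spike-in assays"
            )

    @property
    def n_samples(self) -> int:
        return self.n_control + self.n_gord + self.n_cancer


@dataclass
class GroundTruth:
    """What was planted: signed effects, panel memberships, sample offsets."""

    informative_effects: dict[str, float]  # assay -> Ct shift in cancer
    hkg_ids: list[str]
    spikein_ids: list[str]
    sample_offsets: dict[str, float]

    def __post_init__(self) -> None:
        inf = set(self.informative_effects)
        assert inf.isdisjoint(self.hkg_ids) and inf.isdisjoint(self.spikein_ids)
        assert set(self.hkg_ids).isdisjoint(self.spikein_ids)

    @property
    def informative_ids(self) -> list[str]:
        return list(self.informative_effects)

    def to_json(self) -> str:
        return json.dumps(
            {
                "informative_effects": self.informative_effects,
                "hkg_ids": self.hkg_ids,
                "spikein_ids": self.spikein_ids,
                "sample_offsets": self.sample_offsets,
            },
            indent=2,
        )


def generate_ct_dataset(
    config: SimulationConfig | None = None, seed: int | None = None
) -> tuple[CtMatrix, GroundTruth]:
    """Draw one dataset; deterministic given the seed.

    ``seed`` overrides ``config.seed``; one of the two must be set for a
    reproducible draw (otherwise fresh OS entropy is used).
    """
    config = config or SimulationConfig()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)

    sample_ids = (
        [f"ctrl-{i+1:02d}" for i in range(config.n_control)]
        + [f"gord-{i+1:02d}" for i in range(config.n_gord)]
        + [f"case-{i+1:02d}" for i in range(config.n_cancer)]
    )
    groups = dict(
        zip(
            sample_ids,
            ["control"] * config.n_control
            + ["GORD"] * config.n_gord
            + ["cancer"] * config.n_cancer,
        )
    )
    is_cancer = np.array([groups[s] == "cancer" for s in sample_ids], dtype=float)

    n_target = config.n_assays - config.n_hkg - config.n_spikein
    target_ids = [f"miR-{i+1:03d}" for i in range(n_target)]
    hkg_ids = [f"hkg-{i+1:02d}" for i in range(config.n_hkg)]
    spike_ids = [f"spike-{i+1}" for i in range(config.n_spikein)]
    assay_ids = target_ids + hkg_ids + spike_ids

    baseline = np.concatenate(
        [
            rng.uniform(*config.target_baseline, size=n_target),
            rng.uniform(*config.hkg_baseline, size=config.n_hkg),
            rng.uniform(*config.hkg_baseline, size=config.n_spikein),
        ]
    )
    informative = rng.choice(n_target, size=config.n_informative, replace=False)
    effects = np.zeros(config.n_assays)
    signs = np.array([1.0 if i % 2 == 0 else -1.0 for i in range(config.n_informative)])
    effects[informative] = signs * config.effect_ct

    offsets = rng.normal(0.0, config.sample_offset_sd, size=config.n_samples)
    noise_scale = np.concatenate(
        [
            np.full(n_target, config.noise_sd),
            np.full(config.n_hkg + config.n_spikein, config.hkg_noise_sd),
        ]
    )
    noise = rng.normal(0.0, 1.0, size=(config.n_assays, config.n_samples)) * noise_scale[:, None]
    ct = (
        baseline[:, None]
        + offsets[None, :]
        + effects[:, None] * is_cancer[None, :]
        + noise
    )

    missing = ct >= CYCLE_LIMIT
    if config.dropout_ct50 is not None:
        p_drop = 1.0 / (
            1.0 + np.exp(-(ct - config.dropout_ct50) / config.dropout_scale)
        )
        missing |= rng.random(ct.shape) < p_drop
    ct = np.where(missing, np.nan, ct)

    truth = GroundTruth(
        informative_effects={
            target_ids[i]: float(effects[i]) for i in sorted(informative)
        },
        hkg_ids=hkg_ids,
        spikein_ids=spike_ids,
        sample_offsets={s: float(o) for s, o in zip(sample_ids, offsets)},
    )
    return CtMatrix(assay_ids, sample_ids, ct, groups), truth


def generate_null_dataset(
    config: SimulationConfig | None = None, seed: int | None = None
) -> tuple[CtMatrix, GroundTruth]:
    """Same generative model with no planted class effects."""
    config = config or SimulationConfig()
    return generate_ct_dataset(replace(config, n_informative=0), seed=seed)


def write_dataset(ct: CtMatrix, truth: GroundTruth, outdir) -> dict[str, Path]:
    """Write ct.csv (``Undetermined`` for missing), metadata.csv and
    ground_truth.json in the dialect read by :func:`stavarsel.ct.read_ct_table`."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frame = ct.to_frame().copy().astype(object)
    frame = frame.where(~ct.to_frame().isna(), "Undetermined")
    ct_path = outdir / "ct.csv"
    frame.to_csv(ct_path, index_label="assay_id")
    meta_path = outdir / "metadata.csv"
    pd.DataFrame(
        {"sample_id": ct.sample_ids, "cohort": [ct.group_of_sample[s] for s in ct.sample_ids]}
    ).to_csv(meta_path, index=False)
    truth_path = outdir / "ground_truth.json"
    truth_path.write_text(truth.to_json())
    return {"ct": ct_path, "metadata": meta_path, "ground_truth": truth_path}
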