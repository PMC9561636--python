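"""End-to-end orchestration: simulate/extract -> preprocess -> train -> score
-> screening statistics, with a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field as dc_field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .catalogue import get_catalogue
from .io import write_feature_table
from .prep import preprocess
from .profclass import CVSpec, score_wells, train_reference
from .screenstats import call_hits, z_factor
from .synthgen import (
    DEFAULT_PROFILES,
    NoiseModel,
    PlateSpec,
    make_layout,
    sample_plates,
)

log = logging.getLogger("phenoscreen")


@dataclass
class RunConfig:
    """Everything one pipeline run depends on."""

    panel: str = "panelA"
    out_dir: str = "run"
    n_plates: int = 2
    reference_condition: str = "control"
    positive_condition: str = "mutant"
    compounds: list = dc_field(default_factory=lambda: ["PEP005", "prostratin"])
    n_spiked_per_compound: int = 6
    algorithm: str = "SVM"
    train_fraction: float = 0.8
    n_repeats: int = 25
    z_cut: float = 3.5
    frac_cut: float = 0.2
    r_threshold: float = 0.9
    hit_k: float = 3.0
    noise: dict = dc_field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls().__dict__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full synthetic pipeline; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = f"{config.digest()}_seed{config.seed}"
    stage = "simulate"
    try:
        catalogue = get_catalogue(config.panel)
        spec = PlateSpec(panel=config.panel, seed=config.seed)
        layouts = [
            make_layout(
                spec,
                [(config.reference_condition, "fill"), (config.positive_condition, "fill")],
                compounds=config.compounds,
                n_spiked_per_compound=config.n_spiked_per_compound,
                spike_from=config.positive_condition,
                seed=config.seed + i,
                plate_id=f"P{i + 1}",
            )
            for i in range(config.n_plates)
        ]
        noise = NoiseModel(**config.noise)
        table, _ = sample_plates(layouts, catalogue, DEFAULT_PROFILES, noise, seed=config.seed)
        write_feature_table(table, out / f"features_raw_{tag}.csv")
        log.info("simulated %d plates (%d wells)", config.n_plates, len(table))

        stage = "preprocess"
        if config.reference_condition not in set(table["condition"]):
            raise ValueError(f"reference condition {config.reference_condition!r} not in table")
        proc, report = preprocess(
            table,
            config.reference_condition,
            z_cut=config.z_cut,
            frac_cut=config.frac_cut,
            r_threshold=config.r_threshold,
        )
        write_feature_table(proc, out / f"features_processed_{tag}.csv")
        report.to_json(out / f"prep_report_{tag}.json")

        stage = "train"
        cv = CVSpec(
            train_fraction=config.train_fraction,
            n_repeats=config.n_repeats,
            seed=config.seed,
        )
        model = train_reference(
            proc[proc["spiked"] == 0],
            config.reference_condition,
            config.positive_condition,
            algorithm=config.algorithm,
            cv=cv,
        )
        model.save(out / f"model_{tag}")

        stage = "score"
        scores = score_wells(model, proc)
        scores.to_csv(out / f"scores_{tag}.csv", index=False)

        stage = "stats"
        ref_mask = (scores["condition"] == config.positive_condition) & (scores["spiked"] == 0)
        zres = z_factor(
            scores.loc[ref_mask, "score"],
            scores.loc[scores["condition"] == config.reference_condition, "score"],
        )
        hits = call_hits(
            scores["score"],
            scores.loc[ref_mask, "score"],
            k=config.hit_k,
            conditions=np.where(scores["spiked"] == 1, scores["compound"], scores["condition"]),
        )
        hits.wells.assign(well=scores["well"].values, plate_id=scores["plate_id"].values).to_csv(
            out / f"hits_{tag}.csv", index=False
        )

        manifest = {
            "version": __version__,
            "config": asdict(config),
            "config_hash": config.digest(),
            "seed": config.seed,
            "stage_outputs": sorted(p.name for p in out.iterdir()),
            "accuracy_mean": model.accuracy_mean,
            "accuracy_sem": model.accuracy_sem,
            "z_factor": zres.z,
            "hit_fraction_by_condition": {
                str(kk): float(v) for kk, v in hits.hit_fraction_by_condition.items()
            },
        }
        (out / f"manifest_{tag}.json").write_text(json.dumps(manifest, indent=2))
        (out / f"report_{tag}.txt").write_text(
            "phenoscreen run report\n"
            f"config hash: {config.digest()}  seed: {config.seed}\n"
            f"panel: {config.panel}  plates: {config.n_plates}\n"
            f"{config.algorithm} accuracy: {model.accuracy_mean:.3f} "
            f"+/- SEM {model.accuracy_sem:.3f}\n"
            f"Z-factor ({config.positive_condition} vs {config.reference_condition}): {zres.z:.3f}\n"
            "hit fractions:\n"
            + "".join(
                f"  {kk}: {v:.3f}\n" for kk, v in hits.hit_fraction_by_condition.items()
            )
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    return out
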