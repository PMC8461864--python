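"""End-to-end pipeline: simulate -> vectors -> scores -> evaluation.

The stages mirror the framework's three components: (1) drug effect
vectors from longitudinal EHR-style data, (2) disease sign vectors from
case/control survey data, (3) repurposing scores and their evaluation
against a gold standard.  Each stage reads and writes the plain-text table
contracts defined in :mod:`labcmap.datasets`, so stages can be run
individually or composed by ``run_pipeline`` with identical results.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from labcmap import cscc, disease_signs, evaluation
from labcmap.connect import (
    LabCatalog,
    SignVector,
    harmonize_labs,
    rank_drugs,
    score_matrix,
    write_rankings,
)
from labcmap.datasets import CaseControlDataset, GoldStandard, LongitudinalDataset
from labcmap.synthetic import (
    EHRSimConfig,
    SurveySimConfig,
    TrueDrugEffects,
    generate_ehr,
    generate_gold_standard,
    generate_survey,
    lab_ids,
)

logger = logging.getLogger(__name__)

DEFAULT_K_GRID = (5, 10, 15, 20)


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class PipelineConfig:
    """Validated knobs for a pipeline run.

    Thresholds default to the production setting (drugs with fewer than
    1000 exposed patients and diseases with fewer than 1000 case samples
    are excluded); synthetic desk-scale runs override them in the
    ``simulate`` block.
    """

    out_dir: Path = Path("outputs")
    seed: int = 0
    alpha: float = 0.05
    lambda_strategy: str | float = "cv"
    min_patients_per_drug: int = 1000
    min_samples_per_disease: int = 1000
    k_grid: tuple[int, ...] = DEFAULT_K_GRID
    group_size: int = 80
    n_clusters: int = 2
    simulate: dict[str, Any] = field(default_factory=dict)
    raw: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.min_patients_per_drug < 0 or self.min_samples_per_disease < 0:
            raise ConfigError("minimum-sample thresholds must be >= 0")
        if self.group_size < 1:
            raise ConfigError("group_size must be >= 1")
        ks = tuple(int(k) for k in self.k_grid)
        if any(b <= a for a, b in zip(ks, ks[1:])) or any(k < 1 for k in ks):
            raise ConfigError("k_grid must be ascending positive integers")
        self.k_grid = ks
        if isinstance(self.lambda_strategy, str):
            if self.lambda_strategy != "cv":
                raise ConfigError("lambda_strategy must be 'cv' or a number")
        else:
            self.lambda_strategy = float(self.lambda_strategy)
            if self.lambda_strategy < 0:
                raise ConfigError("fixed lambda must be >= 0")
        self.out_dir = Path(self.out_dir)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config file must hold a mapping")
        known = {
            k: raw[k]
            for k in (
                "out_dir", "seed", "alpha", "lambda_strategy",
                "min_patients_per_drug", "min_samples_per_disease",
                "k_grid", "group_size", "n_clusters", "simulate",
            )
            if k in raw
        }
        known.update({k: v for k, v in overrides.items() if v is not None})
        return cls(raw=raw, **known)

    def config_hash(self) -> str:
        blob = json.dumps(
            {k: v for k, v in self.raw.items()}, sort_keys=True, default=str
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _simulated_world(config: PipelineConfig):
    """Build the planted truth (effects, per-disease shifts) from config.

    The simulated world is structured rather than uniformly random: drug m
    acts on a contiguous footprint of ``effect_labs_per_drug`` labs starting
    at lab m (mod L), even-numbered drugs lowering and odd-numbered drugs
    raising them; disease k elevates a contiguous footprint of
    ``shifted_labs_per_disease`` labs starting at lab k.  Lowering drugs
    whose footprint overlaps a disease's are net complementary (therapeutic
    in this world); raising drugs overlapping it are adverse.
    """
    sim = config.simulate
    if not sim:
        raise ConfigError("no simulate block in config")
    ehr = sim.get("ehr", {})
    n_drugs = int(ehr.get("n_drugs", 20))
    n_labs = int(ehr.get("n_labs", 8))
    magnitude = float(ehr.get("effect_magnitude", 1.0))
    footprint = int(ehr.get("effect_labs_per_drug", 3))
    from labcmap.synthetic import drug_ids

    mat = np.zeros((n_drugs, n_labs))
    for m in range(n_drugs):
        sign = -1.0 if m % 2 == 0 else 1.0
        for off in range(footprint):
            mat[m, (m + off) % n_labs] = sign * magnitude
    effects = TrueDrugEffects(
        matrix=mat, drugs=drug_ids(n_drugs), labs=lab_ids(n_labs)
    )
    survey = sim.get("survey", {})
    n_diseases = int(survey.get("n_diseases", 4))
    labs_per_disease = int(survey.get("shifted_labs_per_disease", 4))
    shift_sds = float(survey.get("shift_sd_units", 0.8))
    lab_sd = float(survey.get("lab_sd", 10.0))
    lab_mean = float(survey.get("lab_mean", 50.0))
    shifts = {}
    for k in range(n_diseases):
        v = np.zeros(n_labs)
        for off in range(labs_per_disease):
            v[(k + off) % n_labs] = shift_sds * lab_sd
        shifts[f"disease_{k:02d}"] = v
    return effects, shifts, lab_mean, lab_sd, survey


def simulate_stage(config: PipelineConfig) -> dict[str, Path]:
    """Generate EHR, survey and gold-standard tables under out_dir."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    effects, shifts, lab_mean, lab_sd, survey = _simulated_world(config)
    ehr_cfg = config.simulate.get("ehr", {})
    ehr_config = EHRSimConfig(
        n_patients=int(ehr_cfg.get("n_patients", 150)),
        n_drugs=len(effects.drugs),
        n_labs=len(effects.labs),
        measurements_per_patient=tuple(ehr_cfg.get("measurements_per_patient", (6, 10))),
        baseline_mean=float(ehr_cfg.get("baseline_mean", 50.0)),
        baseline_sd=float(ehr_cfg.get("baseline_sd", 10.0)),
        noise_sd=float(ehr_cfg.get("noise_sd", 1.0)),
        exposure_prob=float(ehr_cfg.get("exposure_prob", 0.15)),
        seed=config.seed,
    )
    dataset = generate_ehr(ehr_config, effects)
    paths = {"ehr": out / "ehr.tsv"}
    dataset.to_tsv(paths["ehr"])

    n_labs = len(effects.labs)
    for i, (dz, shift) in enumerate(sorted(shifts.items())):
        cc = generate_survey(
            SurveySimConfig(
                disease_id=dz,
                n_cases=int(survey.get("n_cases", 400)),
                n_controls=int(survey.get("n_controls", 400)),
                lab_means=tuple([lab_mean] * n_labs),
                lab_sds=tuple([lab_sd] * n_labs),
                disease_shifts=tuple(shift),
                labs=tuple(lab_ids(n_labs)),
                seed=config.seed + 1 + i,
            )
        )
        p = out / f"survey_{dz}.tsv"
        cc.to_tsv(p)
        paths[f"survey_{dz}"] = p

    gold = generate_gold_standard(effects, shifts)
    paths["gold"] = out / "gold_standard.csv"
    gold.to_csv(paths["gold"])
    return paths


def drug_vectors_stage(config: PipelineConfig, ehr_path: Path) -> cscc.DrugEffectVectors:
    dataset = LongitudinalDataset.from_tsv(ehr_path)
    vectors = cscc.build_drug_effect_vectors(
        dataset,
        alpha=config.alpha,
        lambda_strategy=config.lambda_strategy,
        min_patients=config.min_patients_per_drug,
        seed=config.seed,
    )
    vectors.to_csv(
        config.out_dir / "drug_vectors.csv", config.out_dir / "drug_vector_stats.csv"
    )
    return vectors


def disease_vectors_stage(
    config: PipelineConfig, survey_paths: list[Path]
) -> list[SignVector]:
    vectors: list[SignVector] = []
    frames = []
    for p in survey_paths:
        cc = CaseControlDataset.from_tsv(p)
        for dz in cc.diseases:
            n_cases = int((cc.table[f"status_{dz}"] == 1).sum())
            if n_cases < config.min_samples_per_disease:
                logger.info(
                    "excluding disease %s: %d case samples < %d",
                    dz, n_cases, config.min_samples_per_disease,
                )
                continue
            vectors.append(
                disease_signs.build_disease_vector(cc, dz, alpha=config.alpha)
            )
        _, stats = disease_signs.disease_stats_table(cc, alpha=config.alpha)
        frames.append(stats)
    if not vectors:
        raise ConfigError("no disease passed the minimum-sample threshold")
    disease_signs.write_disease_vectors(vectors, config.out_dir / "disease_vectors.csv")
    pd.concat(frames, ignore_index=True).to_csv(
        config.out_dir / "disease_vector_stats.csv", index=False
    )
    return vectors


def score_stage(
    config: PipelineConfig,
    drug_vectors: cscc.DrugEffectVectors,
    disease_vectors: list[SignVector],
) -> pd.DataFrame:
    """Harmonize lab catalogs (identity aliases) and compute the score matrix."""
    drug_labs = {lab: lab for lab in drug_vectors.signs.columns}
    dz_labs = {lab: lab for v in disease_vectors for lab in v.catalog}
    catalog = harmonize_labs(drug_labs, dz_labs)
    drugs = [
        SignVector(d, drug_vectors.signs.loc[d, list(catalog)])
        for d in drug_vectors.signs.index
    ]
    diseases = [
        SignVector(v.entity_id, v.entries.loc[list(catalog)]) for v in disease_vectors
    ]
    matrix = score_matrix(drugs, diseases)
    matrix.to_csv(config.out_dir / "score_matrix.csv")
    write_rankings(matrix, config.out_dir / "rankings")
    return matrix


def evaluate_stage(
    config: PipelineConfig, matrix: pd.DataFrame, gold: GoldStandard
) -> pd.DataFrame:
    rows = []
    fe_frames = []
    for dz in matrix.columns:
        ranked = rank_drugs(matrix, dz)
        gold_set = gold.drugs_for(dz)
        if not gold_set:
            logger.warning("no gold-standard drugs for %s; skipping", dz)
            continue
        row: dict[str, Any] = {"disease_id": dz}
        for k in config.k_grid:
            if k <= len(ranked):
                row[f"precision_at_{k}"] = evaluation.precision_at_k(ranked, gold_set, k)
        fe = evaluation.fold_enrichment(ranked, gold_set, config.group_size)
        row["fe_slope"] = evaluation.fe_trend(fe) if len(fe.fe) >= 2 else np.nan
        rows.append(row)
        f = fe.to_frame()
        f.insert(0, "disease_id", dz)
        fe_frames.append(f)
    result = pd.DataFrame(rows)
    result.to_csv(config.out_dir / "evaluation.csv", index=False)
    if fe_frames:
        pd.concat(fe_frames, ignore_index=True).to_csv(
            config.out_dir / "fold_enrichment.csv", index=False
        )
    return result


def cluster_stage(config: PipelineConfig, matrix: pd.DataFrame) -> None:
    k = min(config.n_clusters, *matrix.shape)
    row_order, col_order, _, _ = evaluation.bicluster(matrix, k, k, seed=config.seed)
    evaluation.write_clustered_matrix(
        matrix, row_order, col_order, config.out_dir / "clustered_scores.csv"
    )


def run_pipeline(config: PipelineConfig) -> pd.DataFrame:
    """Run every stage and write all artifacts plus a run manifest."""
    config.out_dir.mkdir(parents=True, exist_ok=True)
    paths = simulate_stage(config)
    drug_vecs = drug_vectors_stage(config, paths["ehr"])
    survey_paths = [p for k, p in sorted(paths.items()) if k.startswith("survey_")]
    dz_vecs = disease_vectors_stage(config, survey_paths)
    matrix = score_stage(config, drug_vecs, dz_vecs)
    gold = GoldStandard.from_csv(paths["gold"])
    result = evaluate_stage(config, matrix, gold)
    cluster_stage(config, matrix)

    from labcmap import __version__

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    (config.out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return result
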