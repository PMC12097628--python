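"""End-to-end orchestration: features -> statistics -> replication.

A single YAML config drives the run.  Each dataset (``en``, ``el``) is
either generated synthetically or loaded from a metadata CSV plus
transcript directory (and optional CoNLL-U parse directory), embedded
with the deterministic fixture providers, and summarized into one
feature row per subject.  Covariates are screened on the pooled table,
group and MMSE GLMs run per dataset, and English effects are checked
for replication in Greek.  Identical config + seed yields identical
outputs; a manifest records the config hash and library versions.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .corpus_io import describe_groups, impute_missing, load_cohort, tokenize
from .embedding_backends import (
    FixtureBimodalEncoder,
    GammaSurprisalScorer,
    HashContextualEmbedder,
    HashStaticEmbedder,
)
from .semantic_metrics import MEASURE_COLUMNS, extract_features
from .stats_pipeline import (
    assess_replication,
    results_to_frame,
    run_group_analysis,
    run_mmse_analysis,
    screen_covariates,
    verdicts_to_frame,
)
from .syntax_metrics import averaged_dependency_distance, read_conllu
from .synthetic_data import default_spec, features_from_cohort, generate_cohort

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised when the pipeline config fails validation."""


@dataclass
class DatasetConfig:
    language: str
    source: str = "synthetic"  # "synthetic" | "files"
    metadata: Path | None = None
    transcripts: Path | None = None
    parses: Path | None = None
    spec_overrides: dict = field(default_factory=dict)


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: Path = Path("semspace_out")
    datasets: list[DatasetConfig] = field(default_factory=list)
    provider_dim: int = 64
    provider_entropy_bits: float = 6.0
    provider_alignment: float = 0.6
    fdr_alpha: float = 0.05
    gof_alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        datasets = []
        for lang, section in (raw.get("datasets") or {}).items():
            section = section or {}
            datasets.append(
                DatasetConfig(
                    language=lang,
                    source=section.get("source", "synthetic"),
                    metadata=Path(section["metadata"]) if "metadata" in section else None,
                    transcripts=Path(section["transcripts"]) if "transcripts" in section else None,
                    parses=Path(section["parses"]) if "parses" in section else None,
                    spec_overrides=section.get("spec_overrides", {}) or {},
                )
            )
        providers = raw.get("providers") or {}
        return cls(
            seed=int(raw.get("seed", 0)),
            output_dir=Path(raw.get("output_dir", "semspace_out")),
            datasets=datasets,
            provider_dim=int(providers.get("dim", 64)),
            provider_entropy_bits=float(providers.get("entropy_bits", 6.0)),
            provider_alignment=float(providers.get("alignment", 0.6)),
            fdr_alpha=float(raw.get("fdr_alpha", 0.05)),
            gof_alpha=float(raw.get("gof_alpha", 0.05)),
        )

    def validate(self) -> None:
        if not self.datasets:
            raise ConfigError("config lists no datasets")
        for a in ("fdr_alpha", "gof_alpha"):
            v = getattr(self, a)
            if not 0.0 < v < 1.0:
                raise ConfigError(f"{a} must lie in (0, 1), got {v}")
        for ds in self.datasets:
            if ds.language not in ("en", "el"):
                raise ConfigError(f"unknown dataset language {ds.language!r}")
            if ds.source == "files":
                for name in ("metadata", "transcripts"):
                    p = getattr(ds, name)
                    if p is None or not Path(p).exists():
                        raise ConfigError(
                            f"dataset {ds.language!r}: {name} path missing or absent ({p})"
                        )
                if ds.parses is not None and not Path(ds.parses).exists():
                    raise ConfigError(f"dataset {ds.language!r}: parses path absent ({ds.parses})")
            elif ds.source != "synthetic":
                raise ConfigError(f"dataset {ds.language!r}: unknown source {ds.source!r}")


# ---------------------------------------------------------------------------
# feature assembly


def _features_from_files(ds: DatasetConfig, cfg: PipelineConfig) -> tuple[pd.DataFrame, list]:
    records = impute_missing(load_cohort(ds.metadata, ds.transcripts))
    lang = ds.language
    static = HashStaticEmbedder(dim=cfg.provider_dim, seed=cfg.seed)
    contextual = HashContextualEmbedder(dim=cfg.provider_dim, seed=cfg.seed)
    scorer = GammaSurprisalScorer(cfg.provider_entropy_bits, seed=cfg.seed)
    bimodal = FixtureBimodalEncoder(
        dim=cfg.provider_dim, seed=cfg.seed, alignment=cfg.provider_alignment
    )
    rows = []
    for rec in records:
        tok = tokenize(rec.transcript, lang)
        add = math.nan
        if ds.parses is not None:
            parse_path = Path(ds.parses) / f"{rec.subject_id}.conllu"
            if parse_path.is_file():
                parses = read_conllu(parse_path)
                if parses:
                    add = averaged_dependency_distance(parses)
        feats = extract_features(
            tok,
            static_provider=static,
            contextual_provider=contextual,
            scorer=scorer,
            bimodal_provider=bimodal,
            image_id=f"stimulus-{lang}",
            add=add,
            subject_id=rec.subject_id,
        )
        rows.append(
            {
                "subject_id": rec.subject_id,
                "group": rec.group,
                "language": rec.language,
                "group_pad": 1.0 if rec.group == "pAD" else 0.0,
                "language_el": 1.0 if rec.language == "el" else 0.0,
                "age": rec.age,
                "sex_female": 1.0 if rec.sex == "female" else 0.0,
                "education": rec.education,
                "mmse": rec.mmse,
                **feats.as_dict(),
            }
        )
    return pd.DataFrame(rows), records


def _dataset_features(ds: DatasetConfig, cfg: PipelineConfig) -> tuple[pd.DataFrame, list]:
    if ds.source == "files":
        return _features_from_files(ds, cfg)
    spec = default_spec(ds.language, seed=cfg.seed, **ds.spec_overrides)
    cohort = generate_cohort(spec)
    return features_from_cohort(cohort), cohort.records


# ---------------------------------------------------------------------------
# full run


def run_all(config: PipelineConfig) -> dict[str, Path]:
    """Execute the whole analysis; returns the written output paths."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    features: dict[str, pd.DataFrame] = {}
    all_records = []
    for ds in config.datasets:
        feats, records = _dataset_features(ds, config)
        features[ds.language] = feats
        all_records.extend(records)
        path = out / f"features_{ds.language}.csv"
        feats.to_csv(path, index=False, float_format="%.10g")
        outputs[f"features_{ds.language}"] = path

    desc = describe_groups(
        all_records,
        features={
            name: {
                row.subject_id: getattr(row, name)
                for feats in features.values()
                for row in feats.itertuples(index=False)
            }
            for name in ("word_count", "subword_count", "word_ttr", "subword_ttr")
        },
    )
    desc_path = out / "descriptives.csv"
    desc.to_csv(desc_path, index=False, float_format="%.10g")
    outputs["descriptives"] = desc_path

    pooled = pd.concat(features.values(), ignore_index=True)
    screened, screen_table = screen_covariates(pooled, alpha=config.fdr_alpha)
    screen_path = out / "covariate_screen.csv"
    screen_table.to_csv(screen_path, index=False, float_format="%.10g")
    outputs["covariate_screen"] = screen_path

    group_results: dict[str, list] = {}
    mmse_results: dict[str, list] = {}
    group_frames, mmse_frames = [], []
    for lang, feats in features.items():
        g_res, g_fail = run_group_analysis(feats, screened, gof_alpha=config.gof_alpha)
        m_res, m_fail = run_mmse_analysis(feats, screened, gof_alpha=config.gof_alpha)
        for name, fail in {**g_fail, **m_fail}.items():
            logger.warning("dataset %s: model for %s failed: %s", lang, name, fail)
        group_results[lang] = g_res
        mmse_results[lang] = m_res
        group_frames.append(results_to_frame(g_res, dataset=lang))
        mmse_frames.append(results_to_frame(m_res, dataset=lang))

    group_path = out / "group_regressions.csv"
    pd.concat(group_frames, ignore_index=True).to_csv(
        group_path, index=False, float_format="%.10g"
    )
    outputs["group_regressions"] = group_path
    mmse_path = out / "mmse_regressions.csv"
    pd.concat(mmse_frames, ignore_index=True).to_csv(mmse_path, index=False, float_format="%.10g")
    outputs["mmse_regressions"] = mmse_path

    if "en" in group_results and "el" in group_results:
        verdicts = []
        for focal, results in (("group_pad", group_results), ("mmse", mmse_results)):
            en_by_measure = {r.measure: r for r in results["en"]}
            el_by_measure = {r.measure: r for r in results["el"]}
            for measure in en_by_measure.keys() & el_by_measure.keys():
                verdicts.append(
                    assess_replication(en_by_measure[measure], el_by_measure[measure], focal)
                )
        rep_path = out / "replication.csv"
        verdicts_to_frame(verdicts).to_csv(rep_path, index=False, float_format="%.10g")
        outputs["replication"] = rep_path

    manifest = {
        "semspace_version": __version__,
        "seed": config.seed,
        "config_sha256": _config_hash(config),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "outputs": sorted(p.name for p in outputs.values()),
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
    outputs["manifest"] = manifest_path
    return outputs


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(
        {
            "seed": config.seed,
            "datasets": [
                {
                    "language": d.language,
                    "source": d.source,
                    "metadata": str(d.metadata),
                    "transcripts": str(d.transcripts),
                    "parses": str(d.parses),
                    "spec_overrides": d.spec_overrides,
                }
                for d in config.datasets
            ],
            "provider_dim": config.provider_dim,
            "provider_entropy_bits": config.provider_entropy_bits,
            "provider_alignment": config.provider_alignment,
            "fdr_alpha": config.fdr_alpha,
            "gof_alpha": config.gof_alpha,
        },
        sort_keys=True,
    )
    return hashlib.sha256(blob.encode("utf-8")).hexdigest()
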