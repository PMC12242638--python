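"""End-to-end protocol: curate -> diversity-select -> screen -> evaluate.

``run_protocol`` wires the stages over a run directory, recording a
manifest (parameters, seed, input checksums, stage outputs) so a run can
be reproduced byte-identically from its config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from phorescreen import curation, evaluation, screening
from phorescreen.pharmacophore import PharmacophoreModel, builtin_model
from phorescreen.synthetic import (
    PlantedLibrarySpec,
    make_activity_table,
    make_planted_feature_library,
)

log = logging.getLogger("phorescreen")


@dataclass
class RunConfig:
    """Parameters of one end-to-end run (serializable to JSON/YAML)."""

    out_dir: str
    seed: int = 7
    model: str = "ROCK1"              # builtin name or path to a model JSON
    activities_csv: Optional[str] = None   # None -> synthetic activity table
    active_nM: float = 100.0
    inactive_nM: float = 5000.0
    max_mw: float = 550.0
    diversity_threshold: float = 0.5
    max_conformers: int = 200
    require: tuple[str, ...] = ("hinge HBA",)
    # synthetic-stage sizes, used when no activities_csv is given
    n_active: int = 20
    n_inactive: int = 40
    n_intermediate: int = 5
    n_ic50: int = 5
    n_decoys: int = 180
    jitter_sigma: float = 0.3

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text())
        if "require" in data:
            data["require"] = tuple(data["require"])
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _resolve_model(name_or_path: str) -> PharmacophoreModel:
    p = Path(name_or_path)
    if p.suffix == ".json" and p.exists():
        return PharmacophoreModel.from_json(p)
    try:
        return builtin_model(name_or_path)
    except KeyError:
        raise ValueError(
            f"unknown model {name_or_path!r}: not a builtin (ROCK1, ROCK2) "
            "and not an existing model JSON"
        ) from None


def run_protocol(config: RunConfig) -> Path:
    """Run curation, diversity selection, screening and evaluation.

    Stage outputs, a metrics JSON and a manifest land in
    ``config.out_dir``; the directory path is returned. Any stage error
    aborts with the stage name attached.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": [], "outputs": {}}
    model = _resolve_model(config.model)
    manifest["model"] = model.name

    stage = "curate"
    try:
        log.info("stage %s", stage)
        if config.activities_csv is None:
            df, _ = make_activity_table(
                config.n_active, config.n_inactive, config.n_intermediate,
                config.n_ic50, seed=config.seed, out_dir=out,
            )
            csv_path = out / "activities.csv"
        else:
            csv_path = Path(config.activities_csv)
        records, rejects = curation.parse_activity_table(csv_path)
        labeled = curation.classify_activity(
            records, active_nM=config.active_nM, inactive_nM=config.inactive_nM
        )
        actives_kept, actives_removed = curation.apply_structural_filters(
            labeled.actives, max_mw=config.max_mw
        )
        _write_curated(out / "curated.csv", labeled, actives_kept,
                       actives_removed, rejects)
        manifest["stages"].append(stage)
        manifest["counts"] = {
            "records": len(records),
            "rejects": len(rejects),
            "actives": len(labeled.actives),
            "inactives": len(labeled.inactives),
            "excluded": len(labeled.excluded),
            "actives_after_filters": len(actives_kept),
        }
    except Exception as e:
        raise RuntimeError(f"stage {stage!r} failed: {e}") from e

    stage = "diversity"
    try:
        log.info("stage %s", stage)
        reps, labels = curation.diversity_select(
            actives_kept, distance_threshold=config.diversity_threshold
        )
        import pandas as pd

        pd.DataFrame(
            {
                "compound_id": [c.compound_id for c in actives_kept],
                "cluster": labels,
                "is_representative": [
                    c.compound_id in {r.compound_id for r in reps} for c in actives_kept
                ],
            }
        ).to_csv(out / "diversity_clusters.csv", index=False)
        manifest["stages"].append(stage)
        manifest["counts"]["diversity_clusters"] = int(len(reps))
    except Exception as e:
        raise RuntimeError(f"stage {stage!r} failed: {e}") from e

    stage = "screen"
    try:
        log.info("stage %s", stage)
        spec = PlantedLibrarySpec(
            model=model,
            n_actives=max(1, len(reps)),
            n_decoys=config.n_decoys,
            jitter_sigma=config.jitter_sigma,
            seed=config.seed,
        )
        library, truth_labels = make_planted_feature_library(spec)
        ranked = screening.screen_library(
            library, model, max_conformers=config.max_conformers,
            require=config.require,
        )
        _write_ranked(out / "ranked.csv", ranked)
        manifest["stages"].append(stage)
    except Exception as e:
        raise RuntimeError(f"stage {stage!r} failed: {e}") from e

    stage = "evaluate"
    try:
        log.info("stage %s", stage)
        scores = [r.best_score for r in ranked]
        labels01 = [truth_labels[r.compound_id] for r in ranked]
        roc = evaluation.roc_auc(scores, labels01)
        metrics = {
            "auc": roc.auc,
            "n_actives": roc.n_actives,
            "n_decoys": roc.n_decoys,
            "ef_0.1": evaluation.enrichment_factor(scores, labels01, 0.1),
        }
        (out / "metrics.json").write_text(json.dumps(metrics, indent=2) + "\n")
        manifest["stages"].append(stage)
        manifest["metrics"] = metrics
    except Exception as e:
        raise RuntimeError(f"stage {stage!r} failed: {e}") from e

    for f in sorted(out.glob("*.csv")) + sorted(out.glob("*.json")):
        if f.name != "manifest.json":
            manifest["outputs"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    config.to_json(out / "run_config.json")
    return out


def _write_curated(path: Path, labeled, kept, removed, rejects) -> None:
    import pandas as pd

    rows = []
    kept_ids = {c.compound_id for c in kept}
    for rec in labeled.actives:
        rows.append(
            {"compound_id": rec.compound_id, "canonical_smiles": rec.smiles,
             "label": "active" if rec.compound_id in kept_ids else "active_filtered",
             "reason": ""}
        )
    for rec in labeled.inactives:
        rows.append({"compound_id": rec.compound_id, "canonical_smiles": rec.smiles,
                     "label": "inactive", "reason": ""})
    for rec, reason in labeled.excluded:
        rows.append({"compound_id": rec.compound_id, "canonical_smiles": rec.smiles,
                     "label": "excluded", "reason": reason})
    for row, reason in rejects:
        rows.append({"compound_id": str(row.get("compound_id", "?")),
                     "canonical_smiles": str(row.get("smiles", "")),
                     "label": "rejected", "reason": reason})
    pd.DataFrame(rows).to_csv(path, index=False)


def _write_ranked(path: Path, ranked) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "compound_id": [r.compound_id for r in ranked],
            "score": [r.best_score for r in ranked],
            "rmsd": [r.best_rmsd for r in ranked],
            "matched_labels": [";".join(r.matched_labels) for r in ranked],
            "hbond_ok": [r.hbond_ok for r in ranked],
        }
    ).to_csv(path, index=False)
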