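"""End-to-end pipeline runner with configuration, manifests and
reproducibility plumbing.

A run executes, in order and under stage toggles: simulate (synthetic
study generation) -> hitcall -> featurize -> train -> validate ->
analyze.  Every artifact is written under the run directory and listed
in ``manifest.json`` with a content digest; rerunning a completed run
directory without ``force`` is a no-op.  A single global seed fans out
to the per-stage random streams by fixed offsets, so one knob controls
the whole run.

Configurations are YAML documents validated strictly (unknown keys are
errors) against :class:`RunConfig`.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import analytics, featurization, hitcalling, modeling, synthetic
from .hitcalling import HitCallingConfig
from .synthetic import SyntheticConfig


class PipelineError(RuntimeError):
    """A stage-tagged pipeline failure."""


class StageToggles(BaseModel):
    model_config = {"extra": "forbid", "populate_by_name": True}
    simulate: bool = True
    hitcall: bool = True
    featurize: bool = True
    train: bool = True
    validate_: bool = Field(default=True, alias="validate")
    analyze: bool = True


class InputPaths(BaseModel):
    """External inputs used when the corresponding stage is disabled."""

    model_config = {"extra": "forbid"}
    measurements: str | None = None
    alignment: str | None = None
    substrates: str | None = None
    activity: str | None = None


class ModelingConfig(BaseModel):
    model_config = {"extra": "forbid"}
    n_models: int = 10
    presence_threshold: float = 0.70
    hyperparams: dict = Field(default_factory=dict)


class AnalyticsConfig(BaseModel):
    model_config = {"extra": "forbid"}
    positions: list[int] = Field(default_factory=list)
    min_substrates: int = 0
    make_plots: bool = False


class RunConfig(BaseModel):
    model_config = {"extra": "forbid"}

    out_dir: str
    seed: int = 0
    force: bool = False
    stages: StageToggles = Field(default_factory=StageToggles)
    inputs: InputPaths = Field(default_factory=InputPaths)
    synthetic: SyntheticConfig = Field(default_factory=SyntheticConfig)
    hitcalling: HitCallingConfig | None = None
    drop_inactive_enzymes: bool = True
    near_zero_variance: bool = False
    modeling: ModelingConfig = Field(default_factory=ModelingConfig)
    analytics: AnalyticsConfig = Field(default_factory=AnalyticsConfig)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.model_validate(raw)

    def to_yaml(self, path) -> None:
        # `force` is an execution flag, not part of the scientific run
        # description, so the echoed config stays identical across reruns.
        with open(path, "w") as fh:
            yaml.safe_dump(
                json.loads(self.model_dump_json(by_alias=True, exclude={"force"})),
                fh,
                sort_keys=True,
            )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _read_alignment_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest dict.

    Stage failures are re-raised as :class:`PipelineError` tagged with
    the failing stage.  Completed run directories (manifest present) are
    left untouched unless ``config.force``.
    """
    out = Path(config.out_dir)
    manifest_path = out / "manifest.json"
    if manifest_path.exists() and not config.force:
        return json.loads(manifest_path.read_text())
    out.mkdir(parents=True, exist_ok=True)

    # Global seed fan-out: the synthetic stage uses the run seed directly;
    # modelling resample seeds 1..n and the final split seed 0 are fixed
    # offsets of the deterministic per-stage streams.
    syn_cfg = config.synthetic.model_copy(update={"seed": config.seed})

    manifest: dict = {"seed": config.seed, "stages": {}, "files": {}}
    files: list[Path] = []

    def record(stage: str, status: str) -> None:
        manifest["stages"][stage] = status

    def run_stage(name: str, enabled: bool, fn):
        if not enabled:
            record(name, "skipped")
            return None
        try:
            result = fn()
        except Exception as err:
            record(name, f"failed: {err}")
            manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
            raise PipelineError(f"stage {name!r} failed: {err}") from err
        record(name, "ok")
        return result

    # -- simulate -----------------------------------------------------------
    substrates = None
    alignment = None

    def _simulate():
        nonlocal substrates, alignment
        paths = synthetic.write_run(syn_cfg, out / "synthetic")
        alignment = _read_alignment_fasta(paths["alignment"])
        frame = pd.read_csv(paths["substrates"], sep="\t")
        substrates = [
            synthetic.SubstrateRecord(
                substrate_id=r.substrate_id,
                smiles=r.smiles,
                route=r.route,
                special_case=r.special_case,
                evaluation_time=None if pd.isna(r.evaluation_time) else float(r.evaluation_time),
            )
            for r in frame.itertuples()
        ]
        files.extend(Path(p) for p in paths.values())
        return paths

    sim_paths = run_stage("simulate", config.stages.simulate, _simulate)

    def _resolve(name: str, simulated_key: str | None = None) -> Path:
        configured = getattr(config.inputs, name)
        if configured:
            return Path(configured)
        if sim_paths and simulated_key in sim_paths:
            return Path(sim_paths[simulated_key])
        raise PipelineError(
            f"missing dependency: no {name!r} input configured and the simulate stage "
            "did not provide one"
        )

    if substrates is None and (config.stages.hitcall or config.stages.featurize):
        frame = pd.read_csv(_resolve("substrates", "substrates"), sep="\t")
        substrates = [
            synthetic.SubstrateRecord(
                substrate_id=r.substrate_id,
                smiles=r.smiles,
                route=r.route,
                special_case=r.special_case,
                evaluation_time=None if pd.isna(r.evaluation_time) else float(r.evaluation_time),
            )
            for r in frame.itertuples()
        ]

    # -- hitcall ------------------------------------------------------------
    activity: hitcalling.ActivityMatrix | None = None

    def _hitcall():
        nonlocal activity
        measurements = pd.read_csv(_resolve("measurements", "measurements"))
        hc_cfg = config.hitcalling or synthetic.default_hitcalling_config(substrates)
        activity = hitcalling.call_hits(
            measurements, hc_cfg, drop_inactive_enzymes=config.drop_inactive_enzymes
        )
        path = out / "activity_matrix.csv"
        activity.to_csv(path)
        prov_path = out / "activity_provenance.json"
        prov_path.write_text(
            json.dumps(
                {f"{e}|{s}": v for (e, s), v in sorted(activity.provenance.items())},
                indent=2,
                sort_keys=True,
                default=str,
            )
        )
        files.extend([path, prov_path])

    run_stage("hitcall", config.stages.hitcall, _hitcall)

    if activity is None and (
        config.stages.featurize or config.stages.train or config.stages.validate_ or config.stages.analyze
    ):
        activity = hitcalling.ActivityMatrix.from_csv(_resolve("activity", None))

    # -- featurize ----------------------------------------------------------
    table: featurization.FeatureTable | None = None

    def _featurize():
        nonlocal table, alignment
        if alignment is None:
            alignment = _read_alignment_fasta(_resolve("alignment", "alignment"))
        span = tuple(syn_cfg.signature_span) if config.stages.simulate else None
        block = featurization.trim_to_signature(alignment, span=span)
        enzyme_features = featurization.atchley_encode_alignment(block)
        chem = featurization.chemical_feature_table(synthetic.substrates_to_frame(substrates))
        table = featurization.build_feature_table(
            enzyme_features,
            chem,
            activity,
            featurization.VarianceFilterConfig(near_zero=config.near_zero_variance),
        )
        path = out / "feature_table.csv"
        table.to_csv(path)
        meta = out / "feature_metadata.json"
        meta.write_text(
            json.dumps(
                {"provenance": table.provenance, "removed_features": table.removed_features},
                indent=2,
                sort_keys=True,
            )
        )
        files.extend([path, meta])

    run_stage("featurize", config.stages.featurize, _featurize)

    if table is None and (config.stages.train or config.stages.validate_):
        raise PipelineError("missing dependency: train/validate need the featurize stage")

    # -- train --------------------------------------------------------------
    def _train():
        result = modeling.run_consensus_pipeline(
            table,
            n_models=config.modeling.n_models,
            presence_threshold=config.modeling.presence_threshold,
            hyperparams=config.modeling.hyperparams,
        )
        imp = out / "ensemble_importances.csv"
        result.importances.to_csv(imp, index_label="feature")
        cons = out / "consensus_features.txt"
        cons.write_text("\n".join(result.consensus_features) + "\n")
        fin = out / "final_importances.csv"
        result.final_importances.rename("scaled_importance").to_csv(fin, index_label="feature")
        metrics = out / "final_metrics.json"
        metrics.write_text(json.dumps(result.final_metrics, indent=2, sort_keys=True))
        files.extend([imp, cons, fin, metrics])

    run_stage("train", config.stages.train, _train)

    # -- validate -----------------------------------------------------------
    def _validate():
        for group_by, tag in (("chemical", "loco"), ("enzyme", "loeo")):
            report = modeling.leave_one_group_out(
                table, group_by=group_by, hyperparams=config.modeling.hyperparams
            )
            path = out / f"validation_{tag}.csv"
            report.folds.to_csv(path, index=False)
            files.append(path)

    run_stage("validate", config.stages.validate_, _validate)

    # -- analyze ------------------------------------------------------------
    def _analyze():
        linkage, labels = analytics.jaccard_dendrogram(
            activity, min_substrates=config.analytics.min_substrates
        )
        link_path = out / "jaccard_linkage.csv"
        pd.DataFrame(linkage, columns=["left", "right", "height", "size"]).to_csv(
            link_path, index=False
        )
        newick_path = out / "jaccard_dendrogram.nwk"
        newick_path.write_text(analytics.linkage_to_newick(linkage, labels) + "\n")
        corr_path = out / "substrate_correlation.csv"
        analytics.substrate_correlation(activity).to_csv(corr_path, index_label="substrate_id")
        res = analytics.pca_biplot(activity)
        scores_path = out / "pca_scores.csv"
        res.scores.to_csv(scores_path, index_label="enzyme_id")
        load_path = out / "pca_loadings.csv"
        res.loadings.to_csv(load_path, index_label="substrate_id")
        classes_path = out / "promiscuity_classes.tsv"
        pd.DataFrame(
            [vars(c) for c in analytics.classify_promiscuity(activity)]
        ).to_csv(classes_path, sep="\t", index=False)
        files.extend([link_path, newick_path, corr_path, scores_path, load_path, classes_path])
        if config.analytics.positions and alignment is not None:
            _, logos = analytics.promiscuity_logos(
                activity, alignment, config.analytics.positions
            )
            logo_path = out / "logo_frequencies.csv"
            analytics.logo_frequency_table(logos).to_csv(logo_path, index=False)
            files.append(logo_path)
        if config.analytics.make_plots:
            files.extend(
                Path(p)
                for p in analytics.plot_analytics(
                    activity, out / "plots", config.analytics.positions or None, alignment
                )
            )

    run_stage("analyze", config.stages.analyze, _analyze)

    config.to_yaml(out / "run_config.yaml")
    files.append(out / "run_config.yaml")
    manifest["files"] = {
        str(p.relative_to(out)): _sha256(p) for p in sorted(set(files)) if p.exists()
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
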