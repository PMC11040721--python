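"""End-to-end experiment orchestration.

``run_experiment`` executes generate -> prep -> split -> train -> predict ->
evaluate from one :class:`RunConfig`, writing every intermediate table as TSV
plus JSON reports and a run manifest (config hash, library versions, artifact
checksums).  Rerunning with the same config reproduces all artifacts
bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation, io, mc_inference, models, partitioning, synthetic
from .containers import ReliabilitySpec
from .dataprep import deduplicate, filter_correlated, filter_near_zero_variance
from .utils import derive_seed

logger = logging.getLogger("fingertox")

__all__ = ["RunConfig", "run_experiment"]


@dataclass
class RunConfig:
    """Configuration of one synthetic end-to-end experiment."""

    seed: int = 0
    out_dir: str = "run"
    # generator
    n_chem: int = 2000
    n_features: int = 100
    n_blocks: int = 10
    rho: float = 0.5
    prevalence_range: tuple[float, float] = (0.1, 0.4)
    n_assays: int = 3
    sparsity: int = 5
    effect_size: float = 2.0
    share_fraction: float = 0.5
    target_prevalence: float = 0.05
    missing_rate: float = 0.2
    dup_fraction: float = 0.1
    flip_prob: float = 0.1
    # probabilistic-fingerprint reliability
    base_error_range: tuple[float, float] = (0.01, 0.04)
    hard_fraction: float = 0.05
    hard_error: float = 0.12
    # filtering
    freq_cut: float = 19.0
    unique_cut: float = 10.0
    correlation_cutoff: float = 0.9
    # partitioning
    split_k: int = 5
    cv_k: int = 10
    max_sweeps: int = 20
    rl_fraction: float = 0.1
    rl_tolerance: int = 10
    # modelling
    algorithm: str = "random_forest"
    grid: dict = field(default_factory=lambda: {"n_estimators": [200]})
    resample: str | None = None
    net_hidden: tuple[int, ...] = (64,)
    net_epochs: int = 150
    # inference
    mc_samples: int = 2000
    n_grid: tuple[int, ...] = (100, 1000, 2000)
    class_threshold: float = 0.5
    tpr_target: float = 0.9

    def validate(self) -> None:
        checks = [
            (self.n_chem >= 10, "n_chem must be >= 10"),
            (1 <= self.n_blocks <= self.n_features, "need n_features >= n_blocks >= 1"),
            (0.0 <= self.rho < 1.0, "rho must lie in [0, 1)"),
            (0 < self.target_prevalence < 1, "target_prevalence must lie in (0, 1)"),
            (0 <= self.missing_rate < 1, "missing_rate must lie in [0, 1)"),
            (0 < self.correlation_cutoff < 1, "correlation_cutoff must lie in (0, 1)"),
            (0 < self.rl_fraction < 1, "rl_fraction must lie in (0, 1)"),
            (self.sparsity <= self.n_features, "sparsity cannot exceed n_features"),
            (self.mc_samples >= max(self.n_grid), "mc_samples must cover n_grid"),
        ]
        for ok, message in checks:
            if not ok:
                raise ValueError(f"invalid config: {message}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("prevalence_range", "base_error_range", "net_hidden", "n_grid"):
            if key in payload:
                payload[key] = tuple(payload[key])
        cfg = cls(**payload)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name: str):
    logger.info("stage %s: start", name)
    return time.monotonic()


def run_experiment(config: RunConfig) -> Path:
    """Run the full synthetic pipeline; returns the run directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    artifacts: dict[str, str] = {}

    def write_table(name: str, table: pd.DataFrame) -> None:
        path = out / name
        io.write_table(table, path)
        artifacts[name] = _sha256(path)

    def write_json(name: str, payload) -> None:
        path = out / name
        path.write_text(json.dumps(payload, indent=2, default=float))
        artifacts[name] = _sha256(path)

    try:
        # ------------------------------------------------------------ generate
        t0 = _stage("generate")
        fingerprints = synthetic.generate_fingerprints(
            config.n_chem,
            config.n_features,
            n_blocks=config.n_blocks,
            rho=config.rho,
            prevalence_range=config.prevalence_range,
            seed=derive_seed(seed, "fingerprints"),
        )
        truth = synthetic.plant_toxicophores(
            list(fingerprints.columns),
            n_assays=config.n_assays,
            sparsity=config.sparsity,
            effect_size=config.effect_size,
            share_fraction=config.share_fraction,
            target_prevalence=config.target_prevalence,
            fingerprints=fingerprints,
            seed=derive_seed(seed, "toxicophores"),
        )
        labels_clean = synthetic.simulate_labels(
            fingerprints, truth, config.missing_rate, seed=derive_seed(seed, "labels")
        )
        records = synthetic.inject_duplicates(
            labels_clean,
            dup_fraction=config.dup_fraction,
            flip_prob=config.flip_prob,
            seed=derive_seed(seed, "duplicates"),
        )
        reliability = ReliabilitySpec.default(
            list(fingerprints.columns),
            base_error_range=config.base_error_range,
            hard_fraction=config.hard_fraction,
            hard_error=config.hard_error,
            seed=derive_seed(seed, "reliability"),
        )
        probs = synthetic.emulate_probabilistic_fingerprints(
            fingerprints, reliability, seed=derive_seed(seed, "probs")
        )
        write_table("fingerprints.tsv", fingerprints)
        write_table("probs.tsv", probs)
        io.write_records(records, out / "records.tsv")
        artifacts["records.tsv"] = _sha256(out / "records.tsv")
        io.write_planted_model(truth, out / "truth.json")
        artifacts["truth.json"] = _sha256(out / "truth.json")
        logger.info("stage generate: done in %.1fs", time.monotonic() - t0)

        # ---------------------------------------------------------------- prep
        t0 = _stage("prep")
        labels = deduplicate(records)
        write_table("labels.tsv", labels)
        filtered, nzv_report = filter_near_zero_variance(
            fingerprints, freq_cut=config.freq_cut, unique_cut=config.unique_cut
        )
        filtered, corr_report = filter_correlated(filtered, config.correlation_cutoff)
        write_json(
            "filter_report.json",
            {
                "removed_near_zero": nzv_report.removed_near_zero,
                "removed_correlated": corr_report.removed_correlated,
                "cutoff": config.correlation_cutoff,
                "surviving": corr_report.surviving,
            },
        )
        logger.info("stage prep: done in %.1fs", time.monotonic() - t0)

        # --------------------------------------------------------------- split
        t0 = _stage("split")
        rl_ids = partitioning.stratified_subset(
            labels,
            fraction=config.rl_fraction,
            tolerance=config.rl_tolerance,
            seed=derive_seed(seed, "rl_subset"),
        )
        rest = labels.drop(index=rl_ids)
        train_ids, test_ids = partitioning.split_train_test(
            rest,
            k=config.split_k,
            seed=derive_seed(seed, "split"),
            max_sweeps=config.max_sweeps,
        )
        folds = partitioning.make_cv_folds(
            labels.loc[train_ids],
            k=config.cv_k,
            seed=derive_seed(seed, "folds"),
            max_sweeps=config.max_sweeps,
        )
        split = pd.concat(
            [
                pd.Series("real_life", index=rl_ids),
                pd.Series("train", index=train_ids),
                pd.Series("test", index=test_ids),
            ]
        ).rename("split")
        io.write_table(split.to_frame(), out / "split.tsv")
        artifacts["split.tsv"] = _sha256(out / "split.tsv")
        io.write_table(folds.to_frame(), out / "folds.tsv")
        artifacts["folds.tsv"] = _sha256(out / "folds.tsv")
        logger.info("stage split: done in %.1fs", time.monotonic() - t0)

        # --------------------------------------------------------------- train
        t0 = _stage("train")
        X_train = filtered.loc[train_ids]
        X_test = filtered.loc[test_ids]
        y_train = labels.loc[train_ids]
        single = {}
        for assay in labels.columns:
            single[assay] = models.train_single_output(
                X_train,
                y_train[assay],
                algorithm=config.algorithm,
                grid=config.grid,
                folds=folds.loc[train_ids],
                resample=config.resample,
                random_state=derive_seed(seed, f"model:{assay}"),
            )
        net = models.train_multi_output(
            X_train,
            y_train,
            hidden_layer_sizes=config.net_hidden,
            max_epochs=config.net_epochs,
            random_state=derive_seed(seed, "net"),
        )
        logger.info("stage train: done in %.1fs", time.monotonic() - t0)

        # ------------------------------------------------------------- predict
        t0 = _stage("predict")
        probs_rl = probs.loc[rl_ids, filtered.columns]
        mc_rows, naive_rows = [], []
        for family, scorer in (("single", None), ("multi", net)):
            if family == "single":
                for assay, model in single.items():
                    predictor = mc_inference.MonteCarloPredictor(
                        model,
                        n_samples=config.mc_samples,
                        class_threshold=config.class_threshold,
                    )
                    mc = predictor.predict_table(
                        probs_rl, seed=derive_seed(seed, f"mc:{assay}")
                    )
                    mc["assay_id"] = assay
                    mc["model"] = "single"
                    mc_rows.append(mc)
                    for chem_id, p in probs_rl.iterrows():
                        score, cls = mc_inference.predict_naive(model, p)
                        naive_rows.append(
                            {
                                "chem_id": chem_id,
                                "assay_id": assay,
                                "model": "single",
                                "score": score,
                                "final_class": cls,
                            }
                        )
            else:
                predictor = mc_inference.MonteCarloPredictor(
                    scorer,
                    n_samples=config.mc_samples,
                    class_threshold=config.class_threshold,
                )
                mc = predictor.predict_table(probs_rl, seed=derive_seed(seed, "mc:net"))
                mc["model"] = "multi"
                mc_rows.append(mc)
                for chem_id, p in probs_rl.iterrows():
                    scores, classes = mc_inference.predict_naive(scorer, p)
                    for assay, s, c in zip(net.assay_ids_, scores, classes):
                        naive_rows.append(
                            {
                                "chem_id": chem_id,
                                "assay_id": assay,
                                "model": "multi",
                                "score": float(s),
                                "final_class": int(c),
                            }
                        )
        mc_pred = pd.concat(mc_rows, ignore_index=True)
        naive_pred = pd.DataFrame(naive_rows)
        mc_pred.to_csv(out / "predictions_mc.tsv", sep="\t", index=False)
        naive_pred.to_csv(out / "predictions_naive.tsv", sep="\t", index=False)
        artifacts["predictions_mc.tsv"] = _sha256(out / "predictions_mc.tsv")
        artifacts["predictions_naive.tsv"] = _sha256(out / "predictions_naive.tsv")

        convergence = mc_inference.convergence_analysis(
            net, probs_rl, n_grid=config.n_grid, seed=derive_seed(seed, "convergence")
        )
        convergence.to_csv(out / "convergence.tsv", sep="\t", index=False)
        artifacts["convergence.tsv"] = _sha256(out / "convergence.tsv")
        logger.info("stage predict: done in %.1fs", time.monotonic() - t0)

        # ------------------------------------------------------------ evaluate
        t0 = _stage("evaluate")
        y_rl = labels.loc[rl_ids]
        summary = {}
        for family in ("single", "multi"):
            sub = mc_pred[mc_pred["model"] == family]
            scores = sub.pivot(index="chem_id", columns="assay_id", values="mean_score")
            scores = scores.loc[y_rl.index]
            report = evaluation.evaluation_report(
                scores, y_rl, tpr_target=config.tpr_target
            )
            summary[family] = report.per_assay["fpr_at_tpr"].to_dict()
            write_json(f"eval_{family}.json", report.to_json_dict())

        mc_classes = mc_pred.pivot_table(
            index="chem_id", columns=["model", "assay_id"], values="final_class"
        )
        naive_classes = naive_pred.pivot_table(
            index="chem_id", columns=["model", "assay_id"], values="final_class"
        )
        disagreement = evaluation.disagreement_rate(
            mc_classes, naive_classes.loc[mc_classes.index, mc_classes.columns]
        )
        corr = evaluation.assay_correlation(labels)
        flips = (
            convergence.groupby("assay_id")["flipped"].sum().astype(int).to_dict()
        )
        write_json(
            "summary.json",
            {
                "fpr_at_tpr": summary,
                "disagreement_rate": {
                    f"{m}:{a}": float(v) for (m, a), v in disagreement.items()
                },
                "assay_correlation": corr.round(4).to_dict(),
                "convergence_flips": flips,
            },
        )

        lines = [
            "# Synthetic experiment summary",
            "",
            f"Chemicals: {config.n_chem}; assays: {config.n_assays}; "
            f"MC samples: {config.mc_samples}",
            "",
            "## FPR at TPR >= %.2f (real-life-style set, MC predictions)" % config.tpr_target,
            "",
            "| assay | single-output | multi-output |",
            "|---|---|---|",
        ]
        for assay in labels.columns:
            lines.append(
                f"| {assay} | {summary['single'][assay]:.3f} "
                f"| {summary['multi'][assay]:.3f} |"
            )
        lines += [
            "",
            "## Convergence flips per assay (class changed below max N)",
            "",
            *(f"- {a}: {n}" for a, n in flips.items()),
        ]
        (out / "report.md").write_text("\n".join(lines) + "\n")
        artifacts["report.md"] = _sha256(out / "report.md")
        logger.info("stage evaluate: done in %.1fs", time.monotonic() - t0)
    except Exception as exc:  # annotate which stage/artifact context failed
        raise RuntimeError(f"pipeline failed in {out}: {exc}") from exc

    import sklearn

    manifest = {
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True, default=list).encode()
        ).hexdigest(),
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
        },
        "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
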