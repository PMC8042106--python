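"""End-to-end experiment driver: generate -> assemble -> train -> matrix -> attribute.

One :class:`RunConfig` and one seed determine every downstream artifact.  The
run seed fans out through ``numpy.random.SeedSequence`` spawn keys into
independent child streams (library generation, per-pair balancing, per-pair
trial splits, per-(pair, algorithm, trial) inner-CV seeds), so rerunning the
same config reproduces every numeric table and enlarging one dimension does
not perturb the others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from promisig import __version__
from promisig.assembly import (
    PairDataset,
    SplitTrial,
    balance_dataset,
    make_trials,
    write_splits,
)
from promisig.attribution import (
    feature_contributions,
    map_to_atoms,
    substructure_weight_percentile,
)
from promisig.evaluation import (
    PairData,
    PredictionRecord,
    count_predictions,
    records_to_dataframe,
    run_matrix,
    summarize,
)
from promisig.features import FingerprintParams, fingerprint
from promisig.models import ALGORITHMS, CVConfig, FittedClassifier, train
from promisig.synthdata import (
    LibraryConfig,
    PairLibrary,
    generate_library,
    signature_query,
    write_compound_table,
    write_target_table,
)

__all__ = ["RunConfig", "AttributionSummary", "ExperimentResult", "run_experiment"]


@dataclass(frozen=True)
class RunConfig:
    """Everything one experiment needs; built from a single seed by default."""

    library: LibraryConfig = LibraryConfig()
    fingerprint: FingerprintParams = FingerprintParams()
    inner_folds: int = 5
    grids: Mapping[str, Mapping[str, list]] | None = None
    selection_metric: str = "mcc"
    n_trials: int = 10
    algorithms: tuple[str, ...] = ALGORITHMS
    seed: int = 0
    attribution: bool = True
    out_dir: str | None = None

    def __post_init__(self) -> None:
        for a in self.algorithms:
            if a not in ALGORITHMS:
                raise ValueError(f"unknown algorithm {a!r}")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")

    @staticmethod
    def from_seed(seed: int, **overrides) -> "RunConfig":
        """A config whose library and model seeds all derive from one integer."""
        lib_overrides = overrides.pop("library", None)
        library = lib_overrides if lib_overrides is not None else LibraryConfig()
        library = replace(library, seed=seed)
        return RunConfig(library=library, seed=seed, **overrides)


@dataclass
class AttributionSummary:
    """Attribution diagnostics for one pair's SVM models across trials.

    ``max_decision_diff`` is the largest |sum_d fc + b - f(x)| over every SVM
    test prediction, ``max_conservation_diff`` the largest
    |sum_a fw - sum_d fc|.  ``recovery_mean_percentile`` averages, over
    correctly predicted DT test compounds that carry the pair's planted
    fragment, the rank of the fragment atoms' mean weight among the other
    atoms of the compound (1.0 = fragment outranks everything).
    """

    pair_id: str
    fragment_smiles: str
    n_predictions: int
    max_decision_diff: float
    max_conservation_diff: float
    n_recovery_compounds: int
    recovery_mean_percentile: float | None


@dataclass
class ExperimentResult:
    config: RunConfig
    libraries: list[PairLibrary]
    datasets: dict[str, PairDataset]
    pair_data: dict[str, PairData]
    models: dict[tuple[str, str, int], FittedClassifier]
    records: list[PredictionRecord]
    summary: dict
    attribution: dict[str, AttributionSummary]
    manifest: dict

    def records_frame(self):
        return records_to_dataframe(self.records)


def _child_seed(seed: int, *key: int) -> int:
    ss = np.random.SeedSequence(seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31))


def run_experiment(config: RunConfig) -> ExperimentResult:
    """Run the full diagnostic pipeline for one synthetic library.

    Returns the in-memory result; when ``config.out_dir`` is set, also writes
    the compound/target tables, split files, tidy record table, summary JSON,
    attribution JSON and a manifest underneath it.
    """
    libraries = generate_library(config.library)

    datasets: dict[str, PairDataset] = {}
    pair_data: dict[str, PairData] = {}
    fps_by_pair: dict[str, dict[str, tuple]] = {}
    trials_by_pair: dict[str, list[SplitTrial]] = {}

    for p, lib in enumerate(libraries):
        ds = balance_dataset(
            lib.pair, lib.st_a, lib.st_b, lib.dt, seed=_child_seed(config.seed, 1, p)
        )
        trials = make_trials(
            ds, n_trials=config.n_trials, master_seed=_child_seed(config.seed, 2, p)
        )
        compounds = ds.compounds
        fps = {c.compound_id: fingerprint(c.smiles, config.fingerprint) for c in compounds}
        X = np.stack([fps[c.compound_id][0].bits for c in compounds])
        y = np.array([1 if c.klass == "DT" else -1 for c in compounds])
        pid = lib.pair.pair_id
        datasets[pid] = ds
        trials_by_pair[pid] = trials
        fps_by_pair[pid] = fps
        pair_data[pid] = PairData(
            pair=lib.pair,
            compound_ids=[c.compound_id for c in compounds],
            X=X,
            y=y,
            trials=trials,
        )

    models: dict[tuple[str, str, int], FittedClassifier] = {}
    for p, lib in enumerate(libraries):
        pid = lib.pair.pair_id
        data = pair_data[pid]
        for a, algorithm in enumerate(config.algorithms):
            for t in range(config.n_trials):
                rows = data.train_rows(t)
                cv = CVConfig(
                    inner_folds=config.inner_folds,
                    grids=config.grids,
                    selection_metric=config.selection_metric,
                    seed=_child_seed(config.seed, 3, p, a, t),
                )
                models[(pid, algorithm, t)] = train(
                    algorithm, data.X[rows], data.y[rows], cv,
                    pair_id=pid, trial_index=t,
                )

    records = run_matrix(pair_data, models, config.algorithms, config.n_trials)
    summary = summarize(records)

    attribution: dict[str, AttributionSummary] = {}
    if config.attribution and "svm" in config.algorithms:
        for lib in libraries:
            attribution[lib.pair.pair_id] = _attribute_pair(
                lib, pair_data[lib.pair.pair_id], fps_by_pair[lib.pair.pair_id],
                datasets[lib.pair.pair_id], models, config.n_trials,
            )

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "library": {
            "n_pairs": config.library.n_pairs,
            "mode": config.library.mode,
            "n_st_a": config.library.n_st_a,
            "n_st_b": config.library.n_st_b,
            "n_dt": config.library.n_dt,
            "carrier_rate": config.library.carrier_rate,
            "leak_rate": config.library.leak_rate,
            "seed": config.library.seed,
        },
        "fingerprint": {
            "radius": config.fingerprint.radius,
            "n_bits": config.fingerprint.n_bits,
        },
        "n_trials": config.n_trials,
        "algorithms": list(config.algorithms),
        "n_records": len(records),
        "expected_records": count_predictions(
            config.library.n_pairs, config.n_trials, len(config.algorithms)
        ),
    }
    if manifest["n_records"] != manifest["expected_records"]:
        raise RuntimeError(
            "record count does not match the prediction-count formula: "
            f"{manifest['n_records']} vs {manifest['expected_records']}"
        )

    result = ExperimentResult(
        config=config,
        libraries=libraries,
        datasets=datasets,
        pair_data=pair_data,
        models=models,
        records=records,
        summary=summary,
        attribution=attribution,
        manifest=manifest,
    )
    if config.out_dir is not None:
        _write_outputs(result, Path(config.out_dir))
    return result


def _attribute_pair(
    lib: PairLibrary,
    data: PairData,
    fps: Mapping[str, tuple],
    dataset: PairDataset,
    models: Mapping[tuple[str, str, int], FittedClassifier],
    n_trials: int,
) -> AttributionSummary:
    pid = lib.pair.pair_id
    query = signature_query(lib.signature.fragment_smiles)
    smiles_by_id = {c.compound_id: c.smiles for c in dataset.compounds}

    max_decision = 0.0
    max_conserve = 0.0
    n_predictions = 0
    percentiles: list[float] = []

    for t in range(n_trials):
        model = models[(pid, "svm", t)]
        rows = data.test_rows(t)
        decisions = model.decision_function(data.X[rows])
        preds = np.where(decisions > 0, 1, -1)
        for row, f_val, pred in zip(rows, decisions, preds):
            cid = data.compound_ids[row]
            fp, index = fps[cid]
            fw_feat = feature_contributions(model, fp, compound_id=cid)
            max_decision = max(max_decision, abs(fw_feat.total + fw_feat.bias - f_val))
            atoms = map_to_atoms(fw_feat, index, n_atoms=_n_atoms(smiles_by_id[cid]))
            max_conserve = max(max_conserve, abs(atoms.total - fw_feat.total))
            n_predictions += 1
            if data.y[row] == 1 and pred == 1:
                pct = substructure_weight_percentile(
                    smiles_by_id[cid], atoms, query
                )
                if pct is not None:
                    percentiles.append(pct)

    return AttributionSummary(
        pair_id=pid,
        fragment_smiles=lib.signature.fragment_smiles,
        n_predictions=n_predictions,
        max_decision_diff=max_decision,
        max_conservation_diff=max_conserve,
        n_recovery_compounds=len(percentiles),
        recovery_mean_percentile=float(np.mean(percentiles)) if percentiles else None,
    )


_ATOM_COUNTS: dict[str, int] = {}


def _n_atoms(smiles: str) -> int:
    n = _ATOM_COUNTS.get(smiles)
    if n is None:
        from rdkit import Chem

        n = Chem.MolFromSmiles(smiles).GetNumAtoms()
        _ATOM_COUNTS[smiles] = n
    return n


def _write_outputs(result: ExperimentResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    write_compound_table(out / "compounds.tsv", result.libraries)
    write_target_table(out / "targets.tsv", result.libraries)
    splits_dir = out / "splits"
    splits_dir.mkdir(exist_ok=True)
    for pid, data in result.pair_data.items():
        write_splits(splits_dir / f"{pid}.json", pid, data.trials)
    result.records_frame().to_csv(out / "records.tsv", sep="\t", index=False)
    summary_payload = {
        "|".join(key): stats.as_dict() for key, stats in result.summary.items()
    }
    (out / "summary.json").write_text(json.dumps(summary_payload, indent=1))
    attribution_payload = {
        pid: {
            "fragment_smiles": s.fragment_smiles,
            "n_predictions": s.n_predictions,
            "max_decision_diff": s.max_decision_diff,
            "max_conservation_diff": s.max_conservation_diff,
            "n_recovery_compounds": s.n_recovery_compounds,
            "recovery_mean_percentile": s.recovery_mean_percentile,
        }
        for pid, s in result.attribution.items()
    }
    (out / "attribution.json").write_text(json.dumps(attribution_payload, indent=1))
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=1))
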