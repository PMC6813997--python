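"""End-to-end orchestration: from tree + shapes (or scores) to report tables.

The pipeline mirrors the full analysis chain: optional Procrustes alignment
and PCA of landmarks, multivariate phylogenetic signal of the scores,
stepwise multi-peak OU regime search on the leading components, C-metrics
and the Wheatsheaf index for every detected convergent regime (plus any
user-declared focal groups), and ecological association tests.  Every
stochastic stage draws its own sub-seed from the config seed, so a config
re-run is byte-identical.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .convergence_metrics import c_metrics_significance
from .ecology_assoc import EcologyTable, association_table, body_size_anova, chi_square_tests
from .morphometrics import (
    SemilandmarkScheme,
    gpa,
    load_landmark_dir,
    shape_pca,
    slide_semilandmarks,
)
from .phylo_signal import kmult
from .regime_models import surface
from .trees import read_newick_file
from .wheatsheaf import wheatsheaf

__all__ = ["PipelineConfig", "run_pipeline"]

_STAGES = ("morphometrics", "signal", "surface", "cmetrics", "wheatsheaf", "ecology")


@dataclasses.dataclass
class PipelineConfig:
    """Declarative description of one pipeline run.

    Either ``scores`` (a specimens x PCs CSV, index = species) or
    ``landmarks`` (a directory of .pts files named <species>.pts, plus a
    ``scheme`` JSON) must be given for stages past morphometrics.
    ``n_pcs_regimes`` components feed the regime search (default 2, few
    enough for the per-trait OU independence assumption to be palatable);
    ``n_pcs_metrics`` feed the distance-based metrics (default 30, enough
    to capture most shape variance in the emulated study design).
    """

    tree: str
    out_dir: str
    scores: str | None = None
    landmarks: str | None = None
    scheme: str | None = None
    ecology: str | None = None
    stages: tuple[str, ...] = _STAGES
    focal_sets: dict[str, list[str]] = dataclasses.field(default_factory=dict)
    n_pcs_regimes: int = 2
    n_pcs_metrics: int = 30
    n_sim: int = 1000
    n_perm: int = 999
    n_boot: int = 1000
    seed: int = 0
    slide: bool = True

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in _STAGES]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")
        if self.n_pcs_regimes < 1 or self.n_pcs_metrics < 1:
            raise ValueError("PC counts must be >= 1")
        for name, val in (("n_sim", self.n_sim), ("n_perm", self.n_perm), ("n_boot", self.n_boot)):
            if val < 99:
                raise ValueError(f"{name} must be >= 99")

    @staticmethod
    def from_yaml(path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return PipelineConfig(**raw)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o).__name__)


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")


def _write_csv(path: Path, df: pd.DataFrame, index: bool = True) -> None:
    df.to_csv(path, index=index, float_format="%.10g", lineterminator="\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the manifest dictionary.

    Outputs land in ``config.out_dir``: ``scores.csv``, ``signal.json``,
    ``table1.json``/``table1.csv`` (model comparison and OU parameters),
    ``table2.csv`` (C-metrics), ``table3.csv`` (Wheatsheaf), ``assoc.csv``
    and ``anova.json`` (ecology), plus ``manifest.json`` recording seeds,
    stage completion and the package version.  A stage failure is recorded
    in the manifest and re-raised with the stage name; completed outputs
    are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    subseeds = {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(_STAGES, ss.spawn(len(_STAGES)))
    }
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "subseeds": subseeds,
        "config": dataclasses.asdict(config),
        "completed": [],
    }

    def finish(stage: str) -> None:
        manifest["completed"].append(stage)
        _write_json(out / "manifest.json", manifest)

    tree = read_newick_file(config.tree)

    scores_df: pd.DataFrame | None = None
    try:
        if "morphometrics" in config.stages and config.landmarks:
            lmdir = Path(config.landmarks)
            paths = sorted(lmdir.glob("*.pts"))
            labels = [p.stem for p in paths]
            lms = load_landmark_dir(paths, labels)
            if config.slide and config.scheme:
                scheme = SemilandmarkScheme.from_json(Path(config.scheme).read_text())
                lms = slide_semilandmarks(lms, scheme)
            aligned = gpa(lms)
            space = shape_pca(aligned)
            scores_df = space.scores_frame()
            scores_df.index.name = "species"
            _write_csv(out / "scores.csv", scores_df)
            _write_csv(
                out / "variance.csv",
                pd.DataFrame(
                    {
                        "eigenvalue": space.eigenvalues,
                        "variance_pct": space.variance_pct,
                    },
                    index=[f"PC{i+1}" for i in range(space.eigenvalues.size)],
                ),
            )
            finish("morphometrics")
    except Exception as err:
        _write_json(out / "manifest.json", manifest)
        raise PipelineError("morphometrics", err) from err

    if scores_df is None and config.scores:
        scores_df = pd.read_csv(config.scores, index_col=0)

    remaining = [s for s in config.stages if s != "morphometrics"]
    if not remaining:
        return manifest
    if scores_df is None and any(s != "ecology" for s in remaining):
        raise ValueError("no scores available: provide `scores` or landmark inputs")

    if scores_df is not None:
        scores_df = scores_df.loc[list(tree.tip_labels)]

    surface_result = None
    focal_groups: dict[str, list[str]] = dict(config.focal_sets)
    for stage in remaining:
        try:
            if stage == "signal":
                res = kmult(scores_df, tree, n_perm=config.n_perm, seed=subseeds["signal"])
                _write_json(out / "signal.json", res.to_dict())
                finish(stage)
            elif stage == "surface":
                k = min(config.n_pcs_regimes, scores_df.shape[1])
                surface_result = surface(scores_df.iloc[:, :k], tree)
                _write_json(out / "table1.json", surface_result.summary())
                _write_csv(
                    out / "table1.csv",
                    _table1_frame(surface_result),
                    index=False,
                )
                _write_csv(
                    out / "painting.csv",
                    surface_result.painting.to_branch_table(tree),
                    index=False,
                )
                tip_reg = {
                    lab: surface_result.painting.branch_regimes[v]
                    for v, lab in zip(tree.tips, tree.tip_labels)
                }
                for reg in sorted(set(tip_reg.values())):
                    members = sorted(l for l, r in tip_reg.items() if r == reg)
                    n_shifts_in = sum(
                        1 for s in surface_result.shift_branches.values() if s == reg
                    )
                    if n_shifts_in >= 2 and len(members) >= 2:
                        focal_groups.setdefault(f"regime_{reg}", members)
                finish(stage)
            elif stage == "cmetrics":
                m = min(config.n_pcs_metrics, scores_df.shape[1])
                Ym = scores_df.iloc[:, :m]
                rows = []
                for i, (name, members) in enumerate(sorted(focal_groups.items())):
                    res = c_metrics_significance(
                        Ym, tree, members,
                        n_sim=config.n_sim,
                        seed=subseeds["cmetrics"] + i,
                    )
                    row = {"group": name, **res.to_row()}
                    rows.append(row)
                _write_csv(out / "table2.csv", pd.DataFrame(rows), index=False)
                finish(stage)
            elif stage == "wheatsheaf":
                m = min(config.n_pcs_metrics, scores_df.shape[1])
                Ym = scores_df.iloc[:, :m]
                rows = []
                for i, (name, members) in enumerate(sorted(focal_groups.items())):
                    res = wheatsheaf(
                        Ym, tree, members,
                        n_boot=config.n_boot,
                        seed=subseeds["wheatsheaf"] + i,
                    )
                    rows.append({"group": name, **res.to_row()})
                _write_csv(out / "table3.csv", pd.DataFrame(rows), index=False)
                finish(stage)
            elif stage == "ecology":
                if not config.ecology:
                    continue
                eco = EcologyTable.read_csv(config.ecology)
                if surface_result is not None:
                    membership = {
                        lab: surface_result.painting.branch_regimes[v]
                        for v, lab in zip(tree.tips, tree.tip_labels)
                    }
                else:
                    membership = {lab: "X" for lab in tree.tip_labels}
                all_rows = []
                regimes = sorted(
                    {r for r in membership.values()}
                    & {
                        s
                        for s in (
                            surface_result.shift_branches.values()
                            if surface_result
                            else []
                        )
                    }
                ) or sorted(set(membership.values()))
                for reg in regimes:
                    if sum(1 for v in membership.values() if v == reg) == 0:
                        continue
                    all_rows.extend(chi_square_tests(membership, eco, reg))
                _write_csv(out / "assoc.csv", association_table(all_rows), index=False)
                masses = {s: float(eco.data.loc[s, "mass_kg"]) for s in eco.species}
                try:
                    F, d1, d2, p = body_size_anova(masses, membership)
                    _write_json(
                        out / "anova.json",
                        {"F": F, "df1": d1, "df2": d2, "p": p},
                    )
                except ValueError as e:
                    _write_json(out / "anova.json", {"error": str(e)})
                finish(stage)
        except PipelineError:
            raise
        except Exception as err:
            _write_json(out / "manifest.json", manifest)
            raise PipelineError(stage, err) from err
    _write_json(out / "manifest.json", manifest)
    return manifest


def _table1_frame(res) -> pd.DataFrame:
    s = res.summary()
    rows = [
        {"quantity": "aicc_multipeak_ou", "value": s["aicc_multipeak_ou"]},
        {"quantity": "aicc_ou1", "value": s["aicc_ou1"]},
        {"quantity": "aicc_bm", "value": s["aicc_bm"]},
        {"quantity": "n_regimes", "value": s["n_regimes"]},
        {"quantity": "n_shifts", "value": s["n_shifts"]},
        {"quantity": "n_convergent_regimes", "value": s["n_convergent_regimes"]},
        {"quantity": "n_convergent_shifts", "value": s["n_convergent_shifts"]},
        {"quantity": "convergence_fraction", "value": s["convergence_fraction"]},
    ]
    for trait, pars in s["per_trait"].items():
        rows.append({"quantity": f"alpha[{trait}]", "value": pars["alpha"]})
        rows.append({"quantity": f"half_life[{trait}]", "value": pars["half_life"]})
        rows.append({"quantity": f"sigma2[{trait}]", "value": pars["sigma2"]})
        for reg, th in pars["theta"].items():
            rows.append({"quantity": f"theta_{reg}[{trait}]", "value": th})
    return pd.DataFrame(rows)
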