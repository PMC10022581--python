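"""Project-level orchestration: files, entities, metadata, caching, figures.

A project is a directory with a canonical ``rope.json`` describing entities
(reference sequences), imported structure files, and free-form per-model
metadata.  ``run_pipeline`` executes the whole torsion workflow for one
entity — load, admit, extract, refine, tabulate, ordinate — persisting
refined torsions so that re-runs skip the refinement stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .entity import Entity, admit_member, build_torsion_table  # noqa: E402
from .geometry import extract_internal  # noqa: E402
from .refine import RefinementSettings, refine_torsions  # noqa: E402
from .space import ConformationalSpace, TorsionSpace  # noqa: E402
from .structure_io import load_structure  # noqa: E402

log = logging.getLogger(__name__)

PROJECT_SCHEMA = 1
NEUTRAL_COLOR = "lightgray"  # models lacking the metadata key


@dataclass
class MetadataRule:
    """Annotation rule for plotting: continuous color or discrete marker."""

    key: str
    kind: str  # "continuous-color" | "discrete-marker"
    value: object = None  # equality filter for discrete rules
    cmap: str = "viridis"
    marker: str = "^"

    def __post_init__(self):
        if self.kind not in ("continuous-color", "discrete-marker"):
            raise ValueError(f"unknown rule kind {self.kind!r}")


@dataclass
class Project:
    """On-disk state: entities, model files, metadata, computed spaces."""

    directory: Path
    entities: dict[str, str] = field(default_factory=dict)  # name -> sequence
    files: list[str] = field(default_factory=list)
    metadata: dict[str, dict] = field(default_factory=dict)  # model -> {k: v}
    settings: dict = field(default_factory=dict)

    def __post_init__(self):
        self.directory = Path(self.directory)

    @property
    def project_file(self) -> Path:
        return self.directory / "rope.json"

    def to_dict(self) -> dict:
        return {
            "schema": PROJECT_SCHEMA,
            "entities": dict(sorted(self.entities.items())),
            "files": sorted(self.files),
            "metadata": {
                name: dict(sorted(md.items()))
                for name, md in sorted(self.metadata.items())
            },
            "settings": dict(sorted(self.settings.items())),
        }

    def save(self) -> None:
        self.directory.mkdir(parents=True, exist_ok=True)
        text = json.dumps(self.to_dict(), sort_keys=True, indent=1)
        self.project_file.write_text(text + "\n")

    @classmethod
    def load(cls, directory: str | Path) -> "Project":
        directory = Path(directory)
        data = json.loads((directory / "rope.json").read_text())
        return cls(
            directory=directory,
            entities=data.get("entities", {}),
            files=data.get("files", []),
            metadata=data.get("metadata", {}),
            settings=data.get("settings", {}),
        )

    def add_files(self, paths) -> None:
        for p in paths:
            rel = str(p)
            if rel not in self.files:
                self.files.append(rel)

    def add_metadata_table(self, path: str | Path) -> None:
        """Merge a CSV/TSV keyed on model_name in its first column."""
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
        frame = pd.read_csv(path, sep=sep)
        key = frame.columns[0]
        for _, row in frame.iterrows():
            name = str(row[key])
            self.metadata.setdefault(name, {}).update(
                {k: row[k] for k in frame.columns[1:] if pd.notna(row[k])}
            )

    def attach_metadata(self, series: pd.Series) -> None:
        for name, value in series.items():
            if pd.notna(value):
                self.metadata.setdefault(str(name), {})[series.name] = float(value)

    def metadata_frame(self) -> pd.DataFrame:
        return pd.DataFrame.from_dict(self.metadata, orient="index")


def _cache_path(project: Project, model_name: str) -> Path:
    return project.directory / "refined" / f"{model_name}.json"


def refine_member(project: Project, chain, settings=None, force=False):
    """Extract + refine one member, with a torsion cache under refined/."""
    internal = extract_internal(chain)
    cache = _cache_path(project, chain.model_name)
    if cache.exists() and not force:
        data = json.loads(cache.read_text())
        if data.get("atom_count") == internal.n_atoms:
            internal.torsions[:] = np.array(data["torsions"], dtype=float)
            log.info("refinement cache hit for %s", chain.model_name)
            return internal, float(data["fit_rmsd"]), True
    result = refine_torsions(chain, internal, settings)
    cache.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "model": chain.model_name,
        "atom_count": internal.n_atoms,
        "fit_rmsd": result.fit_rmsd,
        "sweeps": result.sweeps_used,
        "converged": result.converged,
        "torsions": [None if not np.isfinite(t) else round(float(t), 9)
                     for t in result.refined.torsions],
    }
    cache.write_text(json.dumps(payload, sort_keys=True, indent=1) + "\n")
    refined = result.refined
    return refined, result.fit_rmsd, False


def run_pipeline(project: Project, entity_name: str,
                 settings: RefinementSettings | None = None
                 ) -> ConformationalSpace:
    """Full torsion workflow for one entity; artifacts land in the project dir.

    Stages: load files -> split into chains -> admit members -> extract
    internal coordinates -> refine torsions (cached) -> torsion table ->
    conformational space.  Unparseable files are reported and skipped.
    """
    if entity_name not in project.entities:
        raise KeyError(f"unknown entity {entity_name!r}")
    entity = Entity(entity_name, project.entities[entity_name])
    skipped: list[str] = []
    n_chains = 0
    for path in project.files:
        full = Path(path)
        if not full.is_absolute():
            full = project.directory / full
        try:
            chains = load_structure(full)
        except Exception as exc:  # noqa: BLE001 - robustness contract
            log.warning("skipping %s: %s", path, exc)
            skipped.append(str(path))
            continue
        for chain in chains:
            n_chains += 1
            admit_member(entity, chain)
    log.info("%s: %d files (%d skipped), %d chains, %d admitted",
             entity_name, len(project.files), len(skipped), n_chains,
             len(entity.members))
    if len(entity.members) < 2:
        raise ValueError(
            f"entity {entity_name!r} has {len(entity.members)} admitted "
            f"member(s); at least 2 required. Skipped files: {skipped}"
        )
    refined = {}
    for chain, _ in entity.members:
        internal, rmsd, cached = refine_member(project, chain, settings)
        refined[chain.model_name] = internal
        log.info("  %s fit %.4f A%s", chain.model_name, rmsd,
                 " (cached)" if cached else "")
    table = build_torsion_table(entity, refined)
    space = TorsionSpace(table).fit()
    out = project.directory / "spaces"
    out.mkdir(parents=True, exist_ok=True)
    space.to_json(out / f"{entity_name}_torsion.json")
    space.to_tsv(out / f"{entity_name}_torsion.tsv")
    project.settings.setdefault("pipeline", {})[entity_name] = {
        "skipped_files": skipped,
        "chains": n_chains,
        "members": len(entity.members),
    }
    run_pipeline.last_entity = entity  # convenient handle for callers
    run_pipeline.last_refined = refined
    return space


def plot_space(space: ConformationalSpace, rules: list[MetadataRule] = (),
               axes: tuple[int, int, int] = (1, 2, 3), rotation: float = 0.0,
               path: str | Path = "space.png",
               metadata: pd.DataFrame | None = None,
               series: list[list[str]] | None = None) -> Path:
    """2D scatter of a rotated view of three chosen axes (1-based indices).

    Continuous-color rules color points by a numeric metadata key (models
    lacking the key render light gray); discrete-marker rules change the
    marker for models matching a value.  ``series`` lists sequences of model
    names to connect with lines (e.g. time points).
    """
    rank = space.projections.shape[1]
    idx = [a - 1 for a in axes]
    if any(a < 0 or a >= rank for a in idx):
        raise IndexError(f"axes {axes} outside computed rank {rank}")
    view = space.projections[:, idx]
    theta = np.radians(rotation)
    rot = np.array([[np.cos(theta), -np.sin(theta), 0.0],
                    [np.sin(theta), np.cos(theta), 0.0],
                    [0.0, 0.0, 1.0]])
    xy = (view @ rot.T)[:, :2]

    names = space.names
    colors = [NEUTRAL_COLOR] * len(names)
    markers = ["o"] * len(names)
    color_values = None
    color_rule = None
    for rule in rules:
        if metadata is None or rule.key not in metadata.columns:
            if rule.kind == "continuous-color":
                raise ValueError(f"no metadata for continuous rule {rule.key!r}")
            continue
        col = metadata[rule.key].reindex(names)
        if rule.kind == "continuous-color":
            if not pd.api.types.is_numeric_dtype(col.dropna().infer_objects()):
                raise ValueError(
                    f"continuous rule on non-numeric metadata {rule.key!r}")
            color_values = pd.to_numeric(col)
            color_rule = rule
        else:
            for i, name in enumerate(names):
                if pd.isna(col.get(name)):
                    continue  # stays light gray: metadata not available
                if rule.value is None or col.get(name) == rule.value:
                    markers[i] = rule.marker
                    colors[i] = "tab:orange"
                elif colors[i] == NEUTRAL_COLOR:
                    colors[i] = "tab:blue"

    fig, ax = plt.subplots(figsize=(6, 5))
    if color_values is not None:
        have = color_values.notna().to_numpy()
        for marker in set(markers):
            pick = np.array([m == marker for m in markers])
            sel = pick & have
            if sel.any():
                sc = ax.scatter(xy[sel, 0], xy[sel, 1],
                                c=color_values.to_numpy()[sel],
                                cmap=color_rule.cmap, marker=marker, s=36)
            sel = pick & ~have
            if sel.any():
                ax.scatter(xy[sel, 0], xy[sel, 1], color=NEUTRAL_COLOR,
                           marker=marker, s=36)
        fig.colorbar(sc, ax=ax, label=color_rule.key)
    else:
        groups: dict[tuple, list[int]] = {}
        for i, (c, m) in enumerate(zip(colors, markers)):
            groups.setdefault((c, m), []).append(i)
        for (c, m), members in groups.items():
            sel = np.array(members)
            ax.scatter(xy[sel, 0], xy[sel, 1], color=c, marker=m, s=36)
    if series:
        pos = {name: i for i, name in enumerate(names)}
        for line in series:
            pts = np.array([xy[pos[n]] for n in line if n in pos])
            if len(pts) >= 2:
                ax.plot(pts[:, 0], pts[:, 1], "-", color="0.4", lw=1)
    ax.set_xlabel(f"view x (axes {axes}, rot {rotation:g} deg)")
    ax.set_ylabel("view y")
    ax.set_title(f"{space.kind} space, {space.n_molecules} molecules")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
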