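"""End-to-end pipeline: fixture/inputs -> clusters -> ids -> statistics.

The configuration is one flat key-value document (YAML).  Outputs are
written into a catalog directory; ``provenance.json`` records the package
version, seed and a hash of the resolved configuration, and stats tables
carry the same hash in a ``#`` comment header.  Re-running with the same
configuration reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Any, Dict, List, Optional

import pandas as pd
import yaml

from . import __version__, io as rio
from .cluster import build_clusters, occupancy_classes
from .domains import domain_consistency, domain_profiles
from .ids import IdScheme, assign_ids
from .occupancy import (
    fit_growth,
    occupancy_histogram,
    simulate_growth,
    shared_cluster_matrix,
    singleton_counts_per_genome,
)
from .synth import SynthConfig, generate_pangenome

DEFAULT_CONFIG: Dict[str, Any] = {
    "mode": "synthetic",          # synthetic | files
    "out_dir": "catalog",
    "seed": 0,
    "min_overlap": 0.5,
    "id_clade": "Os4530",
    "id_group": "POR",
    "id_version": 1,
    "n_permutations": 20,
    # synthetic-mode knobs (SynthConfig defaults apply otherwise)
    "n_genomes": 16,
    "n_core": 500,
    "n_softcore": 100,
    "n_shell": 200,
    "n_cloud": 150,
    # files-mode inputs
    "gff_paths": [],              # list of "genome=path" strings
    "edges_path": "",
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def config_hash(cfg: Dict[str, Any]) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: Optional[Path | str] = None, **overrides: Any) -> Dict[str, Any]:
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(cfg)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(user)
    cfg.update(overrides)
    return cfg


def _write_table(df: pd.DataFrame, path: Path, chash: str, index: bool) -> None:
    with open(path, "w") as fh:
        fh.write(f"# ricepangenes {__version__} config_hash={chash}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.6g")


def run_pipeline(cfg: Dict[str, Any]) -> Path:
    """Run cluster -> assign-ids -> stats -> domains; returns catalog dir."""
    chash = config_hash(cfg)
    out = Path(cfg["out_dir"])

    if cfg["mode"] == "files":
        for entry in cfg["gff_paths"]:
            _, _, p = entry.partition("=")
            if not Path(p).exists():
                raise PipelineError("inputs", FileNotFoundError(p))
        if not Path(cfg["edges_path"]).exists():
            raise PipelineError("inputs", FileNotFoundError(cfg["edges_path"]))

    try:
        if cfg["mode"] == "synthetic":
            synth_cfg = SynthConfig(
                n_genomes=int(cfg["n_genomes"]),
                subfamily_sizes=_scaled_subfamilies(int(cfg["n_genomes"])),
                n_core=int(cfg["n_core"]),
                n_softcore=int(cfg["n_softcore"]),
                n_shell=int(cfg["n_shell"]),
                n_cloud=int(cfg["n_cloud"]),
                seed=int(cfg["seed"]),
            )
            pg = generate_pangenome(synth_cfg, out / "inputs")
            genes = pg.all_genes()
            edges = pg.correspondences
            panel = pg.panel
            assignments = pg.domain_assignments
        else:
            from .models import Source, make_panel

            genes = []
            triples = []
            for entry in cfg["gff_paths"]:
                genome, _, p = entry.partition("=")
                genes.extend(rio.read_gff3(p, genome, Source.PIPELINE))
                triples.append((genome, genome + "_", "indica"))
            panel = make_panel(triples)
            edges = rio.read_correspondences(cfg["edges_path"])
            assignments = []
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("inputs", exc) from exc

    out.mkdir(parents=True, exist_ok=True)

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise PipelineError(name, exc) from exc

    matrix = stage("cluster", lambda: build_clusters(
        genes, edges, panel, min_overlap=float(cfg["min_overlap"])))
    scheme = IdScheme(cfg["id_clade"], cfg["id_group"], int(cfg["id_version"]))
    matrix = stage("assign-ids", lambda: assign_ids(matrix, scheme))
    stage("write-matrix", lambda: rio.write_pangene_matrix(matrix, out / "matrix.tsv"))

    stats_dir = out / "stats"
    stats_dir.mkdir(exist_ok=True)

    def stats_stage():
        hist = occupancy_histogram(matrix)
        _write_table(
            pd.DataFrame(sorted(hist.items()), columns=["occupancy", "n_pangenes"]),
            stats_dir / "occupancy_histogram.tsv", chash, index=False,
        )
        classes = pd.Series([c.value for c in occupancy_classes(matrix)])
        _write_table(
            classes.value_counts().rename_axis("occ_class").to_frame("n_pangenes")
            .sort_index(),
            stats_dir / "occupancy_classes.tsv", chash, index=True,
        )
        singles = singleton_counts_per_genome(matrix)
        _write_table(
            pd.DataFrame(sorted(singles.items()), columns=["genome", "n_singletons"]),
            stats_dir / "singletons.tsv", chash, index=False,
        )
        curve = simulate_growth(
            matrix, n_permutations=int(cfg["n_permutations"]), seed=int(cfg["seed"])
        )
        fits = []
        for model in ("tettelin", "willenbrock"):
            f = fit_growth(curve, model, seed=int(cfg["seed"]))
            fits.append((model, f.omega, f.kappa, f.tau, f.residual_ss))
        _write_table(
            pd.DataFrame(fits, columns=["model", "omega", "kappa", "tau",
                                        "residual_ss"]),
            stats_dir / "growth_fits.tsv", chash, index=False,
        )
        _write_table(shared_cluster_matrix(matrix),
                     stats_dir / "shared_clusters.tsv", chash, index=True)

    stage("stats", stats_stage)

    if assignments:
        dom_dir = out / "domains"
        dom_dir.mkdir(exist_ok=True)

        def domains_stage():
            rep = domain_consistency(matrix, assignments, "Pfam",
                                     seed=int(cfg["seed"]))
            _write_table(
                pd.DataFrame(
                    [(rep.n_annotated, rep.n_consistent)],
                    columns=["n_annotated", "n_consistent"],
                ),
                dom_dir / "consistency.tsv", chash, index=False,
            )
            profs = domain_profiles(matrix, assignments, "Pfam")
            _write_table(
                pd.DataFrame(
                    [(p.domain_acc, p.n_pangenes, p.mean_occupancy, p.category)
                     for p in profs],
                    columns=["domain", "n_pangenes", "mean_occupancy", "category"],
                ),
                dom_dir / "profiles.tsv", chash, index=False,
            )

        stage("domains", domains_stage)

    provenance = {
        "version": __version__,
        "seed": int(cfg["seed"]),
        "config_hash": chash,
        "config": {k: cfg[k] for k in sorted(cfg)},
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return out


def _scaled_subfamilies(n_genomes: int) -> Dict[str, int]:
    """Panel subfamily sizes scaled to n_genomes, keeping the real panel's
    4:1:2:9 proportions as closely as integer counts allow."""
    base = {"japonica": 4, "aromatic": 1, "aus": 2, "indica": 9}
    if n_genomes == 16:
        return base
    keys = list(base)
    raw = {k: base[k] * n_genomes / 16 for k in keys}
    sizes = {k: max(int(raw[k]), 0) for k in keys}
    while sum(sizes.values()) < n_genomes:
        k = max(keys, key=lambda k: raw[k] - sizes[k])
        sizes[k] += 1
    while sum(sizes.values()) > n_genomes:
        k = min((k for k in keys if sizes[k] > 0), key=lambda k: raw[k] - sizes[k])
        sizes[k] -= 1
    return sizes
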