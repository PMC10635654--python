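"""End-to-end orchestration: simulate -> score -> matrices -> graph -> compare.

A :class:`RunConfig` (plain ``key = value`` text, versioned by a
``schema`` key) drives the whole run.  Every output lands in one
directory and is listed, with a SHA-256 content checksum, in a
``manifest.tsv``; identical config + seed gives byte-identical outputs
and therefore identical checksums.  All stage randomness derives from
the single seed via integer sub-seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import sys
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import lr_io
from .delta import classify, percent_change, top_changing
from .interactome_profiles import (
    build_count_matrix,
    build_profile_matrix,
    profile_correlation,
)
from .lr_scoring import ScoringConfig, score_expression
from .multigraph import build_multigraph, centralities
from .synthetic_data import (
    SimulationConfig,
    generate_condition_pair,
    generate_lr_database,
    sample_active_set,
    write_delta_truth,
)

__all__ = ["RunConfig", "run_pipeline", "demo_config", "UNDEFINED"]

SCHEMA_VERSION = 1
# explicit marker for undefined correlation / percent-change entries
UNDEFINED = "undefined"


@dataclass(frozen=True)
class RunConfig:
    """Parameters of a full synthetic two-condition run."""

    seed: int = 0
    condition_early: str = "day2"
    condition_late: str = "day30"
    n_cell_types: int = 6
    cells_per_type: int = 50
    n_background_genes: int = 60
    n_lr_pairs: int = 120
    frac_undirected: float = 0.3
    ligand_pool: int = 0  # 0 = per-pair private genes
    receptor_pool: int = 0
    n_active: int = 80
    effect_size: float = 4.0
    baseline_mean: float = 1.0
    dispersion: float = 0.3
    gain_rate: float = 0.2
    loss_rate: float = 0.2
    n_permutations: int = 1000
    alpha: float = 0.05
    min_frac_expressing: float = 0.10
    epsilon: float = 1e-6
    top_k: int = 25

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "RunConfig":
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        values: dict = {}
        schema = None
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key == "schema":
                schema = int(val)
                continue
            if key not in fields:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
            typ = fields[key]
            if typ in ("int", int):
                values[key] = int(val)
            elif typ in ("float", float):
                values[key] = float(val)
            else:
                values[key] = val
        if schema is None:
            raise ValueError(f"{path}: missing 'schema' key")
        if schema != SCHEMA_VERSION:
            raise ValueError(f"{path}: unsupported schema {schema}")
        return cls(**values)

    def to_text(self) -> str:
        lines = [f"schema = {SCHEMA_VERSION}"]
        for f in dataclasses.fields(self):
            lines.append(f"{f.name} = {getattr(self, f.name)}")
        return "\n".join(lines) + "\n"


def demo_config(seed: int = 17) -> RunConfig:
    """The bundled demo: 6 cell types x 50 cells, 150 genes, 120 LR pairs.

    The 120 pairs draw their partners from shared 45-ligand / 45-receptor
    gene pools, so with 60 background genes the matrix has 150 genes.
    """
    return RunConfig(
        seed=seed,
        n_cell_types=6,
        cells_per_type=50,
        n_background_genes=60,
        n_lr_pairs=120,
        frac_undirected=0.3,
        ligand_pool=45,
        receptor_pool=45,
        n_active=80,
        effect_size=4.0,
        dispersion=0.3,
        gain_rate=0.2,
        loss_rate=0.2,
        n_permutations=1000,
    )


def _sub_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint64)
    return [int(s % (2**31)) for s in state]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _log(message: str, t0: float) -> None:
    print(f"[cci-delta +{time.perf_counter() - t0:7.2f}s] {message}", file=sys.stderr)


def _write_corr(corr, path: Path) -> None:
    corr.values.to_csv(path, sep="\t", na_rep=UNDEFINED)


def run_pipeline(
    config: RunConfig, out_dir: str | os.PathLike, seed: int | None = None
) -> dict[str, str]:
    """Execute all stages; return {relative path: sha256} (the manifest).

    A failing stage aborts the run with the stage named in the raised
    error; the manifest is only written after every stage succeeded.
    """
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    produced: list[Path] = []

    def emit(name: str, writer) -> Path:
        path = out / name
        writer(path)
        produced.append(path)
        return path

    stage = "simulate"
    try:
        seeds = _sub_seeds(config.seed, 3)
        pools = (
            dict(ligand_pool=config.ligand_pool, receptor_pool=config.receptor_pool)
            if config.ligand_pool and config.receptor_pool
            else {}
        )
        db = generate_lr_database(
            config.n_lr_pairs, config.frac_undirected, seed=seeds[0], **pools
        )
        sim = SimulationConfig(
            lr_db=db,
            n_cell_types=config.n_cell_types,
            cells_per_type=config.cells_per_type,
            n_background_genes=config.n_background_genes,
            effect_size=config.effect_size,
            baseline_mean=config.baseline_mean,
            dispersion=config.dispersion,
            gain_rate=config.gain_rate,
            loss_rate=config.loss_rate,
            seed=seeds[2],
        )
        sim = dataclasses.replace(
            sim,
            active_set=sample_active_set(
                db, sim.cell_types, config.n_active, seed=seeds[1],
                distinct_ids=config.n_active <= len(db),
            ),
        )
        expr_early, expr_late, truth = generate_condition_pair(sim)
        emit("lr_db.tsv", lambda p: lr_io.write_lr_database(db, p))
        emit("truth.json", lambda p: write_delta_truth(truth, p))
        for label, expr in (
            (config.condition_early, expr_early),
            (config.condition_late, expr_late),
        ):
            lr_io.write_expression(
                expr, out / f"counts_{label}.tsv", out / f"meta_{label}.tsv"
            )
            produced += [out / f"counts_{label}.tsv", out / f"meta_{label}.tsv"]
        _log("simulate: wrote database, truth and two expression matrices", t0)

        stage = "score"
        scfg = ScoringConfig(
            n_permutations=config.n_permutations,
            alpha=config.alpha,
            min_frac_expressing=config.min_frac_expressing,
            seed=config.seed,
        )
        sigs = {}
        for label, expr in (
            (config.condition_early, expr_early),
            (config.condition_late, expr_late),
        ):
            sig = score_expression(expr, db, scfg, condition=label)
            sigs[label] = sig
            emit(f"sig_means_{label}.txt", lambda p, s=sig: lr_io.write_significant_means(s, p))
            emit(f"scored_{label}.tsv", lambda p, s=sig: lr_io.write_scored_table(s, p))
            _log(f"score[{label}]: {int(sig.table['significant'].sum())} significant "
                 f"of {len(sig)} scored triples", t0)

        stage = "matrices"
        cms = {}
        for label, sig in sigs.items():
            cm = build_count_matrix(sig, cell_types=sim.cell_types)
            cms[label] = cm
            emit(f"count_matrix_{label}.tsv",
                 lambda p, m=cm: m.values.to_csv(p, sep="\t"))
            for axis, tag in (("as-source", "source"), ("as-target", "target")):
                prof = build_profile_matrix(sig, axis, cell_types=sim.cell_types)
                emit(f"profile_{tag}_{label}.tsv",
                     lambda p, m=prof: m.values.to_csv(p, sep="\t"))
                emit(f"corr_profile_{tag}_rows_{label}.tsv",
                     lambda p, m=prof: _write_corr(profile_correlation(m, "rows"), p))
            emit(f"corr_counts_rows_{label}.tsv",
                 lambda p, m=cm: _write_corr(profile_correlation(m, "rows"), p))
            emit(f"corr_counts_columns_{label}.tsv",
                 lambda p, m=cm: _write_corr(profile_correlation(m, "columns"), p))
        _log("matrices: count/profile/correlation tables written", t0)

        stage = "graph"
        for label, sig in sigs.items():
            mg = build_multigraph(sig, db)
            payload = {
                "directed": True,
                "condition": label,
                "nodes": [
                    {"id": n, "kind": k}
                    for n, k in sorted(mg.graph.nodes(data="kind"))
                ],
                "edges": [
                    {"source": u, "target": v, "weight": int(w)}
                    for u, v, w in sorted(mg.graph.edges(data="weight"))
                ],
                "paths": [
                    {
                        "interaction_id": r.interaction_id,
                        "source": r.source,
                        "target": r.target,
                        "directed": r.directed,
                        "paths": [list(p) for p in r.paths],
                    }
                    for r in mg.records
                ],
            }
            emit(f"graph_{label}.json",
                 lambda p, d=payload: Path(p).write_text(
                     json.dumps(d, sort_keys=True, indent=1) + "\n"))
            report = centralities(mg, epsilon=config.epsilon)
            def write_report(p, rep=report):
                with open(p, "w") as fh:
                    fh.write(
                        f"# katz_alpha={rep.alpha!r} epsilon={rep.epsilon!r} "
                        f"lambda_max={rep.lambda_max!r} katz_scale={rep.katz_scale!r}\n"
                    )
                    rep.table.to_csv(fh, sep="\t")
            emit(f"centralities_{label}.tsv", write_report)
        _log("graph: node-link JSON and centrality reports written", t0)

        stage = "compare"
        dc = classify(
            sigs[config.condition_early],
            sigs[config.condition_late],
            db,
            cell_types=sim.cell_types,
        )
        delta_table = dc.table.copy()
        delta_table["change_score"] = (
            delta_table["mean_late"] - delta_table["mean_early"]
        ).abs()
        emit("delta.tsv", lambda p: delta_table.to_csv(p, sep="\t", index=False))
        summaries = []
        for scope in ("pair", "as-source", "as-target", "population-total"):
            cs = percent_change(
                cms[config.condition_early], cms[config.condition_late], scope
            )
            tab = cs.table.reset_index()
            tab.insert(0, "scope", scope)
            summaries.append(tab)
        summary = pd.concat(summaries, ignore_index=True)
        emit("summary.tsv",
             lambda p: summary.to_csv(p, sep="\t", index=False, na_rep=UNDEFINED))
        def write_top(p):
            with open(p, "w") as fh:
                fh.write(
                    "# change_score = |mean_late - mean_early| of significant "
                    "means (missing = 0); ties: gained > lost > stable > absent, "
                    "then lexicographic\n"
                )
                top_changing(dc, k=config.top_k).to_csv(fh, sep="\t", index=False)
        emit("top_changing.tsv", write_top)
        emit("pair_class_counts.tsv",
             lambda p: dc.pair_summary().to_csv(p, sep="\t"))
        counts = dc.class_counts()
        _log(
            "compare: "
            + ", ".join(f"{c}={counts[c]}" for c in ("stable", "lost", "gained", "absent")),
            t0,
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        str(p.relative_to(out)): _sha256(p) for p in sorted(set(produced))
    }
    with open(out / "manifest.tsv", "w") as fh:
        fh.write("path\tsha256\tbytes\n")
        for rel in sorted(manifest):
            fh.write(f"{rel}\t{manifest[rel]}\t{(out / rel).stat().st_size}\n")
    _log(f"done: {len(manifest)} artifacts in {out}", t0)
    return manifest
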