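"""Orchestration: scan -> breakpoints -> statistics as one reproducible run.

A run is described by a YAML config (see :class:`RunConfig`), and produces a
motif-association table (one row per motif set x breakpoint end x direction,
with significance stars at 0.05 / 0.01 / 0.001), enrichment curves out to
D_max, both-ends results, optional per-subgroup reruns, and a JSON manifest
echoing every parameter, seed and convention used.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import (
    DeletionProximityModel,
    MotifBreakpointAssociation,
    _stars,
)
from .breakpoints import (
    filter_by_group,
    read_deletions,
    unique_breakpoints,
)
from .genome import CircularGenome, read_fasta
from .motifs import (
    MotifSet,
    enumerate_repeat_pairs,
    find_ddi_qfp,
    find_intrastrand_qfp,
    find_repeats,
    read_midpoints_tsv,
    repeat_units_to_motifset,
)
from .synthetic import shuffle_genome


class PipelineError(RuntimeError):
    """A stage failure, labelled with the stage that raised it."""


@dataclass
class RunConfig:
    genome: str
    deletions: str
    motif_specs: list = field(default_factory=lambda: [
        {"scanner": "qfp", "min_run": 3},
        {"scanner": "qfp", "min_run": 2},
        {"scanner": "repeats", "k": 11, "repeat_class": "direct"},
        {"scanner": "repeats", "k": 11, "repeat_class": "inverted"},
        {"scanner": "repeats", "k": 11, "repeat_class": "complementary"},
        {"scanner": "repeats", "k": 11, "repeat_class": "inverted_complementary"},
    ])
    d_max: int = 50
    both_ends_d: float = 10.0
    p_convention: str = "at_least_K"
    subgroups: list = field(default_factory=list)  # [{"label":..,"value":..}]
    out_dir: str = "mitoqfp_run"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        for p in (cfg.genome, cfg.deletions):
            if not Path(p).exists():
                raise PipelineError(f"config: referenced path does not exist: {p}")
        return cfg


def build_motif_set(genome: CircularGenome, spec: dict) -> MotifSet:
    """Materialize one motif spec: a builtin scanner by name, or an external
    midpoint TSV (e.g. stem-loop/cruciform midpoints computed elsewhere)."""
    kind = spec.get("scanner", "external")
    if kind == "qfp":
        return find_intrastrand_qfp(genome, int(spec.get("min_run", 2)))
    if kind == "ddi_qfp":
        intra = find_intrastrand_qfp(genome, int(spec.get("min_run", 2)))
        return find_ddi_qfp(genome, int(spec.get("min_run", 2)), intra)
    if kind == "repeats":
        units = find_repeats(genome, int(spec.get("k", 11)),
                             spec.get("repeat_class", "direct"))
        return repeat_units_to_motifset(units, genome.id, L=len(genome),
                                        name=spec.get("name"))
    if kind == "external":
        return read_midpoints_tsv(spec["path"], name=spec.get("name"),
                                  genome_id=genome.id)
    raise PipelineError(f"unknown motif spec {spec!r}")


def _association_rows(motif_sets, deletions, L, d_max):
    rows = []
    curves = []
    for mset in motif_sets:
        if len(mset) == 0:
            continue
        for end in ("5p", "3p"):
            bset = unique_breakpoints(deletions, end)
            model = MotifBreakpointAssociation.from_sets(mset, bset, L)
            res = model.fit(d_max=d_max)
            rows.append(res.summary_row())
            for direction, curve in (
                ("bp_to_motif", res.enrichment_bp_to_motif),
                ("motif_to_bp", res.enrichment_motif_to_bp),
            ):
                df = curve.to_frame()
                df.insert(0, "motif_set", mset.name)
                df.insert(1, "end", end)
                df.insert(2, "direction", direction)
                curves.append(df)
    return pd.DataFrame(rows), (pd.concat(curves, ignore_index=True)
                                if curves else pd.DataFrame())


def run_association_suite(config: RunConfig) -> dict:
    """Run the full motif/breakpoint association analysis.

    Returns a dict of output paths; writes TSV tables and a JSON manifest
    under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load genome"
    try:
        genome = read_fasta(config.genome)
        L = len(genome)
        stage = "load deletions"
        deletions = read_deletions(config.deletions, L=L)
        stage = "scan motifs"
        motif_sets = [build_motif_set(genome, s) for s in config.motif_specs]
        for mset in motif_sets:
            mset.write_tsv(out / f"motifs_{mset.name}.tsv")
        stage = "association statistics"
        table, curves = _association_rows(motif_sets, deletions, L, config.d_max)
        table.to_csv(out / "mda_table.tsv", sep="\t", index=False)
        if not curves.empty:
            curves.to_csv(out / "enrichment_curves.tsv", sep="\t", index=False)
        stage = "both-ends tests"
        be_rows = []
        for mset in motif_sets:
            if len(mset) == 0:
                continue
            res = DeletionProximityModel(deletions, mset, L,
                                         D=config.both_ends_d).fit()
            be_rows.append(dict(motif_set=mset.name, mode=res.mode,
                                D=res.D, n_close=res.n_close, N=res.N,
                                P=res.P, expected=res.expected,
                                p_value=res.p_value,
                                p_value_literal=res.p_value_literal,
                                sig=_stars(res.p_value)))
            elements = getattr(mset, "elements", [])
            if elements and hasattr(elements[0], "repeat_class"):
                pairs = enumerate_repeat_pairs(elements)
                if pairs:
                    pres = DeletionProximityModel(deletions, pairs, L,
                                                  D=config.both_ends_d).fit()
                    be_rows.append(dict(motif_set=f"{mset.name}_pairs",
                                        mode=pres.mode, D=pres.D,
                                        n_close=pres.n_close, N=pres.N,
                                        P=pres.P, expected=pres.expected,
                                        p_value=pres.p_value,
                                        p_value_literal=pres.p_value_literal,
                                        sig=_stars(pres.p_value)))
        pd.DataFrame(be_rows).to_csv(out / "both_ends.tsv", sep="\t", index=False)
        stage = "subgroups"
        sub_tables = []
        for sg in config.subgroups:
            subset = filter_by_group(deletions, sg["label"], sg["value"])
            if not subset:
                continue
            t, _ = _association_rows(motif_sets, subset, L, config.d_max)
            t.insert(0, "subgroup", f"{sg['label']}={sg['value']}")
            sub_tables.append(t)
        if sub_tables:
            pd.concat(sub_tables, ignore_index=True).to_csv(
                out / "mda_subgroups.tsv", sep="\t", index=False)
        stage = "manifest"
        manifest = {
            "package": "mitoqfp",
            "version": __version__,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "genome": {"id": genome.id, "L": L,
                       "composition": genome.base_composition()},
            "deletions": {"path": str(config.deletions), "n": len(deletions)},
            "n_rotational_controls": L - 1,
            "d_max": config.d_max,
            "both_ends_d": config.both_ends_d,
            "p_conventions_reported": ["at_least_K", "greater_than_K"],
            "default_p_convention": config.p_convention,
            "seed": config.seed,
            "motif_sets": {m.name: len(m) for m in motif_sets},
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    except Exception as exc:  # noqa: BLE001 - re-raise with stage label
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc
    return {"out_dir": str(out), "mda_table": str(out / "mda_table.tsv"),
            "both_ends": str(out / "both_ends.tsv"),
            "manifest": str(out / "manifest.json")}


def summarize_motif_count_excess(genome: CircularGenome, motif_spec: dict,
                                 n_shuffles: int, seed: int = 0) -> dict:
    """Is the genome's motif count higher than in composition-matched random
    genomes?  Empirical upper-tail p over composition-preserving shuffles."""
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    actual = len(build_motif_set(genome, motif_spec))
    rng = np.random.default_rng(seed)
    null_counts = []
    for _ in range(n_shuffles):
        g = shuffle_genome(genome, int(rng.integers(0, 2**31 - 1)))
        null_counts.append(len(build_motif_set(g, motif_spec)))
    null_counts = np.asarray(null_counts)
    p = (1 + int(np.count_nonzero(null_counts >= actual))) / (n_shuffles + 1)
    return {
        "actual_count": actual,
        "null_mean": float(null_counts.mean()),
        "null_sd": float(null_counts.std(ddof=1)) if n_shuffles > 1 else 0.0,
        "n_shuffles": n_shuffles,
        "p_value": p,
        "seed": seed,
    }
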