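"""End-to-end pipeline orchestration with manifests and reproducible seeds.

A single structured config drives the stages (simulate, repeats, recomb,
rearrange, sweep, delcall) in dependency order. Every file a stage reads or
writes is recorded in a JSON manifest with its SHA-256 checksum; a stage
refuses to consume an upstream file whose checksum no longer matches what
its producer recorded. Re-running an identical config over identical inputs
is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import deletion, popgen, rearrangement, recombination, repeats as repeats_mod
from .sequences import CircularSequence, read_fasta, write_fasta
from .simulate import SimulationConfig, gen_circular_genome, gen_depth_profiles, gen_population_variants, gen_rearranged_pair, sim_long_reads

__all__ = ["PipelineError", "load_config", "run_pipeline", "STAGES"]

STAGES = ("simulate", "repeats", "recomb", "rearrange", "sweep", "delcall")

_KNOWN_TOP = {"seed", "stages", "simulate", "repeats", "recomb", "rearrange", "sweep", "delcall"}
_KNOWN_STAGE_KEYS = {
    "simulate": set(SimulationConfig.__dataclass_fields__) | {"n_depth_samples", "n_blocks"},
    "repeats": {"min_word", "evalue_max"},
    "recomb": {"flank", "min_identity", "min_pair_length"},
    "rearrange": {"tree"},
    "sweep": {"window", "step", "fst_min", "ratio_min", "maf_min", "max_missing"},
    "delcall": {"threshold", "two_band"},
}


class PipelineError(RuntimeError):
    pass


def load_config(path: str | Path) -> Dict:
    import yaml

    cfg = yaml.safe_load(Path(path).read_text()) or {}
    validate_config(cfg)
    return cfg


def validate_config(cfg: Dict) -> None:
    unknown = set(cfg) - _KNOWN_TOP
    if unknown:
        raise PipelineError(f"unknown config keys: {sorted(unknown)}")
    for stage, keys in _KNOWN_STAGE_KEYS.items():
        block = cfg.get(stage) or {}
        bad = set(block) - keys
        if bad:
            raise PipelineError(f"unknown keys in [{stage}]: {sorted(bad)}")
    for st in cfg.get("stages", []):
        if st not in STAGES and st != "all":
            raise PipelineError(f"unknown stage {st!r}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifest:
    def __init__(self, outdir: Path, cfg: Dict):
        self.path = outdir / "manifest.json"
        if self.path.exists():
            self.data = json.loads(self.path.read_text())
        else:
            self.data = {"config": cfg, "stages": {}}
        self.data["config"] = cfg

    def record(self, stage: str, inputs: Dict[str, str], outputs: Dict[str, str]) -> None:
        self.data["stages"][stage] = {"inputs": inputs, "outputs": outputs}
        self.path.write_text(json.dumps(self.data, indent=2, sort_keys=True) + "\n")

    def expect_output(self, producer: str, path: Path) -> None:
        """Verify an upstream output exists and still matches its checksum."""
        if not path.exists():
            raise PipelineError(f"missing upstream output {path.name} (stage {producer!r} not run?)")
        rec = self.data["stages"].get(producer, {}).get("outputs", {})
        recorded = rec.get(path.name)
        if recorded is not None and recorded != _sha256(path):
            raise PipelineError(
                f"checksum mismatch for {path.name}: file changed since stage {producer!r} wrote it"
            )


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(cfg: Dict, outdir: str | Path, stages: Optional[List[str]] = None) -> Dict:
    """Run the configured stages into ``outdir``; returns the manifest dict."""
    validate_config(cfg)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    todo = list(stages or cfg.get("stages") or STAGES)
    if "all" in todo:
        todo = list(STAGES)
    manifest = _Manifest(out, cfg)
    seed = int(cfg.get("seed", 0))

    sim_block = dict(cfg.get("simulate") or {})
    n_depth_samples = int(sim_block.pop("n_depth_samples", 40))
    n_blocks = int(sim_block.pop("n_blocks", 8))
    sim_cfg = SimulationConfig(seed=seed, **sim_block)

    for stage in todo:
        if stage == "simulate":
            _stage_simulate(sim_cfg, n_depth_samples, n_blocks, out, manifest)
        elif stage == "repeats":
            _stage_repeats(cfg, out, manifest)
        elif stage == "recomb":
            _stage_recomb(cfg, sim_cfg, out, manifest)
        elif stage == "rearrange":
            _stage_rearrange(cfg, out, manifest)
        elif stage == "sweep":
            _stage_sweep(cfg, sim_cfg, out, manifest)
        elif stage == "delcall":
            _stage_delcall(cfg, out, manifest)
        else:
            raise PipelineError(f"unknown stage {stage!r}")
    return manifest.data


def _stage_simulate(sim_cfg: SimulationConfig, n_depth: int, n_blocks: int, out: Path, man: _Manifest) -> None:
    genome, truth = gen_circular_genome(sim_cfg)
    write_fasta([genome], out / "genome.fasta")
    _write_tsv(repeats_mod.repeats_to_frame(truth), out / "repeats_truth.tsv")

    # long reads for the assay on the longest planted pair
    pair = max(truth, key=lambda p: p.length)
    reads = sim_long_reads(genome, pair, sim_cfg)
    write_fasta([CircularSequence(r.id, r.seq) for r in reads], out / "reads.fasta")
    _write_tsv(
        pd.DataFrame([{"read_id": r.id, "label": r.label, "conformation": r.conformation} for r in reads]),
        out / "read_labels.tsv",
    )

    ident, scrambled, k = gen_rearranged_pair(n_blocks, sim_cfg.n_inversions, seed=sim_cfg.seed)
    orders = pd.DataFrame(
        [
            {"genome_id": "identity", "blocks": ",".join(map(str, ident.blocks))},
            {"genome_id": scrambled.genome_id, "blocks": ",".join(map(str, scrambled.blocks))},
        ]
    )
    _write_tsv(orders, out / "orders.tsv")

    vm, sweep_truth = gen_population_variants(sim_cfg)
    popgen.write_vcf(vm, out / "variants.vcf")
    _write_tsv(
        pd.DataFrame({"sample": vm.samples, "group": [vm.populations[s] for s in vm.samples]}),
        out / "pops.tsv",
    )
    _write_tsv(pd.DataFrame(sweep_truth, columns=["start", "end"]), out / "sweep_truth.tsv")

    rng = np.random.default_rng(np.random.SeedSequence((sim_cfg.seed, 6)))
    presence = rng.random(n_depth) < 0.5
    depth = gen_depth_profiles(sim_cfg, n_depth, presence.tolist())
    _write_tsv(depth, out / "depth.tsv")
    groups = ["AW", "AC", "EW", "EC"]
    _write_tsv(
        pd.DataFrame(
            {"sample": depth["sample_id"], "group": [groups[i % 4] for i in range(n_depth)]}
        ),
        out / "groups.tsv",
    )

    outputs = {
        p.name: _sha256(p)
        for p in [
            out / n
            for n in (
                "genome.fasta",
                "repeats_truth.tsv",
                "reads.fasta",
                "read_labels.tsv",
                "orders.tsv",
                "variants.vcf",
                "pops.tsv",
                "sweep_truth.tsv",
                "depth.tsv",
                "groups.tsv",
            )
        ]
    }
    man.record("simulate", {}, outputs)


def _stage_repeats(cfg: Dict, out: Path, man: _Manifest) -> None:
    man.expect_output("simulate", out / "genome.fasta")
    params = cfg.get("repeats") or {}
    genome = read_fasta(out / "genome.fasta")[0]
    pairs = repeats_mod.find_repeats(
        genome,
        min_word=int(params.get("min_word", 7)),
        evalue_max=float(params.get("evalue_max", 1e-6)),
    )
    _write_tsv(repeats_mod.repeats_to_frame(pairs), out / "repeats.tsv")
    size, gc = repeats_mod.genome_stats(genome)
    summ = repeats_mod.repeat_summary(genome, pairs)
    (out / "repeat_summary.json").write_text(
        json.dumps(
            {
                "genome_size": size,
                "gc_content": gc,
                "total_count": summ.total_count,
                "total_length": summ.total_length,
                "per_class": summ.per_class_counts,
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    man.record(
        "repeats",
        {"genome.fasta": _sha256(out / "genome.fasta")},
        {"repeats.tsv": _sha256(out / "repeats.tsv"), "repeat_summary.json": _sha256(out / "repeat_summary.json")},
    )


def _stage_recomb(cfg: Dict, sim_cfg: SimulationConfig, out: Path, man: _Manifest) -> None:
    for producer, name in (("simulate", "genome.fasta"), ("simulate", "reads.fasta"), ("repeats", "repeats.tsv")):
        man.expect_output(producer, out / name)
    params = cfg.get("recomb") or {}
    flank = int(params.get("flank", 200))
    min_ident = float(params.get("min_identity", 99.0))
    min_len = int(params.get("min_pair_length", 500))
    genome = read_fasta(out / "genome.fasta")[0]
    reads = read_fasta(out / "reads.fasta")
    table = pd.read_csv(out / "repeats.tsv", sep="\t")
    rows = []
    for _, r in table.iterrows():
        if r["length"] < min_len:
            continue
        pair = repeats_mod.RepeatPair(
            (int(r["startA"]), int(r["endA"])),
            (int(r["startB"]), int(r["endB"])),
            int(r["length"]),
            float(r["identity"]),
            str(r["orientation"]),
        )
        assay = recombination.build_recombinant_references(genome, pair, flank=flank)
        assay = recombination.assign_reads(reads, assay, min_identity=min_ident, flank_required=flank)
        rows.append(
            {
                "startA": pair.locusA[0],
                "startB": pair.locusB[0],
                "length": pair.length,
                "class": pair.length_class,
                "n_ref": assay.n_ref,
                "n_recomb": assay.n_recomb,
                "n_uninformative": assay.n_uninformative,
                "frequency": recombination.recombination_frequency(assay),
            }
        )
    _write_tsv(pd.DataFrame(rows), out / "recomb.tsv")
    man.record(
        "recomb",
        {n: _sha256(out / n) for n in ("genome.fasta", "reads.fasta", "repeats.tsv")},
        {"recomb.tsv": _sha256(out / "recomb.tsv")},
    )


def _stage_rearrange(cfg: Dict, out: Path, man: _Manifest) -> None:
    man.expect_output("simulate", out / "orders.tsv")
    orders = pd.read_csv(out / "orders.tsv", sep="\t")
    perms = {
        r["genome_id"]: rearrangement.SignedPermutation(
            tuple(int(x) for x in str(r["blocks"]).split(",")), genome_id=r["genome_id"]
        )
        for _, r in orders.iterrows()
    }
    ids = list(perms)
    mat = pd.DataFrame(0, index=ids, columns=ids, dtype=int)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            d = rearrangement.relative_distance(perms[a], perms[b])
            mat.loc[a, b] = mat.loc[b, a] = d
    mat.index.name = "genome_id"
    mat.to_csv(out / "distance_matrix.tsv", sep="\t")
    man.record(
        "rearrange",
        {"orders.tsv": _sha256(out / "orders.tsv")},
        {"distance_matrix.tsv": _sha256(out / "distance_matrix.tsv")},
    )


def _stage_sweep(cfg: Dict, sim_cfg: SimulationConfig, out: Path, man: _Manifest) -> None:
    man.expect_output("simulate", out / "variants.vcf")
    man.expect_output("simulate", out / "pops.tsv")
    params = cfg.get("sweep") or {}
    pops_df = pd.read_csv(out / "pops.tsv", sep="\t")
    populations = dict(zip(pops_df["sample"], pops_df["group"]))
    vm = popgen.read_vcf(out / "variants.vcf", populations, reference_length=sim_cfg.genome_length)
    vm = popgen.filter_variants(
        vm,
        maf_min=float(params.get("maf_min", 0.01)),
        max_missing=float(params.get("max_missing", 0.1)),
    )
    windows = popgen.window_table(
        vm, window=int(params.get("window", 1000)), step=int(params.get("step", 500))
    )
    flagged, regions = popgen.call_sweeps(
        windows,
        fst_min=float(params.get("fst_min", 0.1)),
        ratio_min=float(params.get("ratio_min", 2.0)),
        reference_length=vm.reference_length,
    )
    _write_tsv(flagged, out / "windows.tsv")
    _write_tsv(pd.DataFrame(regions, columns=["start", "end"]), out / "sweep_regions.tsv")
    man.record(
        "sweep",
        {n: _sha256(out / n) for n in ("variants.vcf", "pops.tsv")},
        {n: _sha256(out / n) for n in ("windows.tsv", "sweep_regions.tsv")},
    )


def _stage_delcall(cfg: Dict, out: Path, man: _Manifest) -> None:
    man.expect_output("simulate", out / "depth.tsv")
    man.expect_output("simulate", out / "groups.tsv")
    params = cfg.get("delcall") or {}
    depth = pd.read_csv(out / "depth.tsv", sep="\t")
    groups_df = pd.read_csv(out / "groups.tsv", sep="\t")
    group_map = dict(zip(groups_df["sample"], groups_df["group"]))
    calls = []
    for _, r in depth.iterrows():
        ratio = r["Idep"] / r["Wdep"] if r["Wdep"] > 0 else float("nan")
        call = deletion.classify_presence(
            ratio,
            threshold=float(params.get("threshold", 2.0)),
            two_band=bool(params.get("two_band", False)),
        )
        calls.append(
            deletion.DepthCall(
                r["sample_id"],
                (int(r["region_start"]), int(r["region_end"])),
                float(r["Idep"]),
                float(r["Wdep"]),
                ratio,
                call,
            )
        )
    _write_tsv(
        pd.DataFrame(
            [
                {
                    "sample_id": c.sample_id,
                    "Idep": c.idep,
                    "Wdep": c.wdep,
                    "ratio": c.ratio,
                    "call": c.call,
                }
                for c in calls
            ]
        ),
        out / "calls.tsv",
    )
    table = deletion.carrier_frequencies(calls, group_map)
    _write_tsv(table.groups, out / "carriers.tsv")
    _write_tsv(table.pairwise, out / "carrier_tests.tsv")
    man.record(
        "delcall",
        {n: _sha256(out / n) for n in ("depth.tsv", "groups.tsv")},
        {n: _sha256(out / n) for n in ("calls.tsv", "carriers.tsv", "carrier_tests.tsv")},
    )
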