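"""End-to-end orchestration: simulate -> filter -> profile -> diversity ->
emd -> stats, driven by a single flat YAML config.

Each stage persists its outputs under the run directory and is skipped on
re-run when they already exist, so a run is resumable stage by stage. All
randomness flows from one global seed through per-stage derived seeds
(CRC32 of "seed:stage"), making every stage reproducible independently of
execution order. A manifest records parameters, seeds and SHA-256
checksums of every produced file.
"""

from __future__ import annotations

import copy
import dataclasses
import hashlib
import json
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diversity, emdebruijn, filtering, profiling, stats, synthetic
from .taxonomy import Taxonomy

DEFAULT_CONFIG: dict = {
    "outdir": "run",
    "seed": 7,
    "simulate": {
        "n_phyla": 23,
        "genera_per_phylum": 4,
        "group_sizes": {"Control": 12, "SCZ": 12, "BPD": 12, "ALS": 12},
        "n_reads": 20000,
        "host_length": 20000,
        "markers_per_genus": 2,
        "marker_length_range": [300, 800],
        "error_rate": 0.0,
    },
    "filter": {
        "depth": 100000,
        "min_quality": 20,
        "min_quality_frac": 0.8,
        "complexity_threshold": 7.0,
        "host_k": 21,
        "max_shared_host_kmers": 2,
        "deduplicate": False,
    },
    "profile": {"k": 21, "min_hits": 2},
    "diversity": {"rank": "phylum"},
    "emd": {"k": 6, "mode": "complete", "max_reads_per_sample": 2000},
    "stats": {"target_group": "SCZ", "n_permutations": 1000,
              "control_group": "Control"},
}

_RANGES = {
    ("filter", "depth"): (1, None),
    ("filter", "min_quality"): (0, 60),
    ("filter", "min_quality_frac"): (1e-9, 1.0),
    ("filter", "complexity_threshold"): (0, None),
    ("profile", "k"): (11, 31),
    ("profile", "min_hits"): (1, None),
    ("emd", "k"): (2, 12),
    ("simulate", "n_phyla"): (1, None),
    ("simulate", "genera_per_phylum"): (1, None),
    ("simulate", "n_reads"): (1, None),
    ("stats", "n_permutations"): (1, None),
}


class ConfigError(ValueError):
    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid config:\n" + "\n".join(f"  - {e}" for e in errors))


def validate_config(source) -> dict:
    """Load and validate a config (path, YAML string or dict).

    All validation errors are collected and reported together. Unknown
    keys are rejected; missing keys take their defaults.
    """
    if isinstance(source, dict):
        raw = copy.deepcopy(source)
    else:
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        raw = yaml.safe_load(text) or {}
    errors: list[str] = []
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    for key, val in raw.items():
        if key not in cfg:
            errors.append(f"unknown key {key!r}")
            continue
        if isinstance(cfg[key], dict):
            if not isinstance(val, dict):
                errors.append(f"{key!r} must be a mapping")
                continue
            for sub, sval in val.items():
                if sub not in cfg[key]:
                    errors.append(f"unknown key {key}.{sub}")
                else:
                    cfg[key][sub] = sval
        else:
            cfg[key] = val
    for (sec, name), (lo, hi) in _RANGES.items():
        v = cfg[sec][name]
        if not isinstance(v, (int, float)):
            errors.append(f"{sec}.{name} must be numeric, got {v!r}")
        elif (lo is not None and v < lo) or (hi is not None and v > hi):
            errors.append(f"{sec}.{name}={v} outside [{lo}, {hi}]")
    if cfg["emd"]["mode"] not in ("complete", "observed"):
        errors.append(f"emd.mode must be complete|observed, got {cfg['emd']['mode']!r}")
    if errors:
        raise ConfigError(errors)
    return cfg


def write_config(cfg: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))


def derive_seed(global_seed: int, stage: str) -> int:
    return zlib.crc32(f"{global_seed}:{stage}".encode()) & 0x7FFFFFFF


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class Pipeline:
    """Stage runner over a validated config."""

    def __init__(self, cfg: dict):
        self.cfg = cfg
        self.outdir = Path(cfg["outdir"])
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {"seed": cfg["seed"], "stages": {}}

    # -------------------------------------------------------------- paths
    def _p(self, name: str) -> Path:
        return self.outdir / name

    def _stage_done(self, outputs: list[Path]) -> bool:
        return all(p.exists() for p in outputs)

    def _record(self, stage: str, outputs: list[Path], seed: int | None) -> None:
        self.manifest["stages"][stage] = {
            "seed": seed,
            "outputs": {p.name: _sha256(p) for p in outputs if p.exists()},
            "params": self.cfg.get(stage.split("_")[0], {}),
        }

    # -------------------------------------------------------------- stages
    def stage_simulate(self, resume: bool = True) -> None:
        sim = self.cfg["simulate"]
        seed = derive_seed(self.cfg["seed"], "simulate")
        outs = [self._p(n) for n in ("taxonomy.tsv", "markers.fa", "host.fa",
                                     "design.tsv", "cells.tsv")]
        sample_dir = self._p("reads")
        if resume and self._stage_done(outs) and sample_dir.exists():
            self._record("simulate", outs, seed)
            return
        rng = np.random.default_rng(seed)
        tax = synthetic.build_taxonomy(sim["n_phyla"], sim["genera_per_phylum"],
                                       seed=seed)
        markers = synthetic.simulate_markers(
            tax, sim["markers_per_genus"], tuple(sim["marker_length_range"]),
            seed=seed, k=self.cfg["profile"]["k"])
        host = synthetic.simulate_host_reference(sim["host_length"], seed=seed)
        designs = synthetic.simulate_design(seed=seed, sizes=sim["group_sizes"])
        profiles = synthetic.default_group_profiles(tax, sim["n_phyla"])

        tax.to_tsv(self._p("taxonomy.tsv"))
        synthetic.write_fasta([(m.marker_id, m.sequence) for m in markers],
                              self._p("markers.fa"))
        synthetic.write_fasta([("host_chr1", host)], self._p("host.fa"))
        synthetic.write_design_table(designs, self._p("design.tsv"))

        sample_dir.mkdir(exist_ok=True)
        truth_rows = {}
        true_alpha = {}
        for d in designs:
            prof = profiles[d.group]
            sseed = int(rng.integers(2**31))
            ab = synthetic.draw_sample_abundances(prof, seed=sseed,
                                                  n_phyla=sim["n_phyla"])
            reads, origin = synthetic.simulate_sample_reads(
                d, ab, markers, host,
                knobs={"n_reads": sim["n_reads"],
                       "error_rate": sim["error_rate"]},
                seed=sseed)
            synthetic.write_fastq(reads, sample_dir / f"{d.sample_id}.fastq")
            synthetic.write_origin_table(origin, sample_dir / f"{d.sample_id}.origin.tsv")
            truth_rows[d.sample_id] = ab
            n_gen = sim["genera_per_phylum"]
            phy = ab.reshape(sim["n_phyla"], n_gen).sum(axis=1)
            true_alpha[d.sample_id] = diversity.inverse_simpson(phy) if phy.sum() else np.nan
        pd.DataFrame.from_dict(truth_rows, orient="index",
                               columns=tax.genera).to_csv(
            self._p("true_abundances.tsv"), sep="\t", index_label="sample_id")
        alpha_s = pd.Series(true_alpha).sort_index()
        cells = synthetic.simulate_cell_proportions(alpha_s.values, seed=seed)
        synthetic.write_cell_table(cells, list(alpha_s.index), self._p("cells.tsv"))
        self._record("simulate", outs + [self._p("true_abundances.tsv")], seed)

    def stage_filter(self, resume: bool = True) -> None:
        fcfg = self.cfg["filter"]
        seed = derive_seed(self.cfg["seed"], "filter")
        cand_dir = self._p("candidates")
        report_path = self._p("filter_reports.tsv")
        if resume and report_path.exists() and cand_dir.exists():
            self._record("filter", [report_path], seed)
            return
        cand_dir.mkdir(exist_ok=True)
        design = pd.read_csv(self._p("design.tsv"), sep="\t")
        host = _read_fasta_seqs(self._p("host.fa"))
        index = filtering.build_host_index(host, fcfg["host_k"])
        rows = []
        for sid in design["sample_id"]:
            reads = filtering.read_fastq(self._p("reads") / f"{sid}.fastq")
            cfg = filtering.FilterConfig(
                depth=fcfg["depth"], subsample_seed=derive_seed(seed, sid),
                min_quality=fcfg["min_quality"],
                min_quality_frac=fcfg["min_quality_frac"],
                complexity_threshold=fcfg["complexity_threshold"],
                host_k=fcfg["host_k"],
                max_shared_host_kmers=fcfg["max_shared_host_kmers"],
                deduplicate=fcfg["deduplicate"])
            cands, report = filtering.run_filter(reads, index, cfg)
            filtering.write_candidates_fasta(cands, cand_dir / f"{sid}.fa")
            rows.append({"sample_id": sid, **{k: v for k, v in report.__dict__.items()
                                              if not isinstance(v, list)}})
        pd.DataFrame(rows).to_csv(report_path, sep="\t", index=False)
        self._record("filter", [report_path], seed)

    def stage_profile(self, resume: bool = True) -> None:
        pcfg = self.cfg["profile"]
        outs = [self._p("abundance_genus.tsv"), self._p("abundance_phylum.tsv")]
        if resume and self._stage_done(outs):
            self._record("profile", outs, None)
            return
        tax = Taxonomy.from_tsv(self._p("taxonomy.tsv"))
        markers = [synthetic.MarkerGene(n, n.rsplit("_m", 1)[0], s)
                   for n, s in _read_fasta(self._p("markers.fa"))]
        index = profiling.build_index(markers, tax, pcfg["k"])
        design = pd.read_csv(self._p("design.tsv"), sep="\t")
        profiles = {}
        for sid in design["sample_id"]:
            seqs = [s for _, s in _read_fasta(self._p("candidates") / f"{sid}.fa")]
            profiles[sid] = profiling.profile_sample(seqs, index, pcfg["min_hits"])
        genus = profiling.table_from_profiles(profiles, tax, "genus")
        phylum = profiling.aggregate_rank(genus, "phylum")
        genus.to_tsv(self._p("abundance_genus.tsv"), relative=False)
        phylum.to_tsv(self._p("abundance_phylum.tsv"), relative=False)
        self._record("profile", outs, None)

    def stage_diversity(self, resume: bool = True) -> None:
        outs = [self._p("alpha.tsv"), self._p("beta.tsv"), self._p("gamma.tsv")]
        if resume and self._stage_done(outs):
            self._record("diversity", outs, None)
            return
        table = self._load_rank_table()
        design = pd.read_csv(self._p("design.tsv"), sep="\t", index_col="sample_id")
        res = diversity.diversity_result(table, design["group"])
        res.alpha.to_csv(self._p("alpha.tsv"), sep="\t", index_label="sample_id",
                         header=["alpha"])
        res.beta.to_tsv(self._p("beta.tsv"))
        res.gamma.to_csv(self._p("gamma.tsv"), sep="\t", index_label="group",
                         header=["gamma"])
        self._record("diversity", outs, None)

    def stage_emd(self, resume: bool = True) -> None:
        ecfg = self.cfg["emd"]
        seed = derive_seed(self.cfg["seed"], "emd")
        outs = [self._p("emd.tsv"), self._p("emd_pcs.tsv")]
        if resume and self._stage_done(outs):
            self._record("emd", outs, seed)
            return
        design = pd.read_csv(self._p("design.tsv"), sep="\t")
        rng = np.random.default_rng(seed)
        dists = {}
        for sid in design["sample_id"]:
            seqs = [s for _, s in _read_fasta(self._p("candidates") / f"{sid}.fa")]
            cap = ecfg["max_reads_per_sample"]
            if len(seqs) > cap:
                idx = rng.choice(len(seqs), size=cap, replace=False)
                seqs = [seqs[i] for i in idx]
            dists[sid] = emdebruijn.kmer_counts(seqs, ecfg["k"])
        dm = emdebruijn.pairwise_emd(dists, mode=ecfg["mode"])
        dm.to_tsv(self._p("emd.tsv"))
        emdebruijn.ordinate(dm, 3).to_csv(self._p("emd_pcs.tsv"), sep="\t",
                                          index_label="sample_id")
        self._record("emd", outs, seed)

    def stage_stats(self, resume: bool = True) -> None:
        scfg = self.cfg["stats"]
        seed = derive_seed(self.cfg["seed"], "stats")
        out = self._p("stats_summary.json")
        if resume and out.exists():
            self._record("stats", [out], seed)
            return
        design = pd.read_csv(self._p("design.tsv"), sep="\t", index_col="sample_id")
        alpha = pd.read_csv(self._p("alpha.tsv"), sep="\t", index_col="sample_id")["alpha"]
        beta = diversity.DistanceMatrix.from_tsv(self._p("beta.tsv"), "bray_curtis")
        emd_dm = diversity.DistanceMatrix.from_tsv(self._p("emd.tsv"), "emdebruijn")
        table = self._load_rank_table()
        target = scfg["target_group"]
        control = scfg["control_group"]
        ok = alpha.dropna().index
        summary: dict = {}
        contrasts = stats.alpha_group_contrasts(alpha.loc[ok], design.loc[ok],
                                                target, drop_aliased=True)
        summary["alpha_contrasts"] = contrasts.to_dict()
        case = (design["group"] == target).astype(int)
        cc = design.index[design["group"].isin([target, control])].intersection(ok)
        summary["logistic_delta_r2"] = stats.logistic_delta_r2(
            case.loc[cc], alpha.loc[cc], design.loc[cc]).to_dict()
        perm = stats.permanova(beta, design.loc[beta.ids, "group"],
                               scfg["n_permutations"], seed)
        summary["permanova_bray_curtis"] = perm.to_dict()
        summary["permanova_emdebruijn"] = stats.permanova(
            emd_dm, design.loc[emd_dm.ids, "group"],
            scfg["n_permutations"], seed).to_dict()
        sub_ids = [s for s in beta.ids if design.loc[s, "group"] in (target, control)]
        sub = _subset_dm(beta, sub_ids)
        summary["beta_pair_groups"] = stats.beta_pair_groups(
            sub, design.loc[sub_ids, "group"], n_perm=999, seed=seed)
        summary["presence_tests"] = (
            stats.presence_tests(table, design["group"]).reset_index()
            .to_dict(orient="records"))
        coords = pd.read_csv(self._p("emd_pcs.tsv"), sep="\t", index_col="sample_id")
        summary["ordination_association"] = stats.ordination_association(
            coords, case, design).to_dict()
        cells = pd.read_csv(self._p("cells.tsv"), sep="\t", index_col="sample_id")
        summary["cell_proportion_association"] = (
            stats.cell_proportion_association(alpha.loc[ok], cells.loc[ok],
                                              design.loc[ok])
            .reset_index().to_dict(orient="records"))
        emd_vs_beta = emdebruijn.correlate_ordinations(emd_dm, beta)
        summary["emd_vs_bray_curtis"] = emd_vs_beta
        out.write_text(json.dumps(_jsonify(summary), indent=2))
        self._record("stats", [out], seed)

    # -------------------------------------------------------------- helpers
    def _load_rank_table(self) -> profiling.AbundanceTable:
        tax = Taxonomy.from_tsv(self._p("taxonomy.tsv"))
        rank = self.cfg["diversity"]["rank"]
        genus = profiling.AbundanceTable.from_tsv(
            self._p("abundance_genus.tsv"), "genus", tax, relative=False)
        return profiling.aggregate_rank(genus, rank)

    def run_all(self, resume: bool = True) -> dict:
        for stage in (self.stage_simulate, self.stage_filter, self.stage_profile,
                      self.stage_diversity, self.stage_emd, self.stage_stats):
            stage(resume=resume)
        self._p("manifest.json").write_text(json.dumps(_jsonify(self.manifest), indent=2))
        return self.manifest


def run_all(config, resume: bool = True) -> dict:
    return Pipeline(validate_config(config)).run_all(resume=resume)


def _subset_dm(dm: diversity.DistanceMatrix, ids: list[str]) -> diversity.DistanceMatrix:
    pos = [dm.ids.index(s) for s in ids]
    return diversity.DistanceMatrix(ids, dm.values[np.ix_(pos, pos)], dm.metric)


def _read_fasta(path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def _read_fasta_seqs(path) -> list[str]:
    return [s for _, s in _read_fasta(path)]


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if dataclasses.is_dataclass(obj):
        return _jsonify(dataclasses.asdict(obj))
    return obj
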