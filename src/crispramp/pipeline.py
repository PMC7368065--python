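"""End-to-end orchestration: predict -> design -> simulate -> quantify -> report.

A single YAML/dict configuration drives a fully synthetic, fully reproducible
run: a reference with planted off-target sites is generated, candidate sites
are predicted, an enrichment guide is designed for the on-target locus, the
cleave-and-amplify enrichment is simulated over rounds, per-round read sets
are fabricated at the simulated mutant fractions, and each is quantified back.
The report distinguishes model-dependent columns (anything downstream of the
escape-probability defaults or the cleavage efficiency c) from data-derived
columns, and every stage records the SHA-256 of its inputs for provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .design import EditingLocus, design_indel_enrichment_guide
from .enrichment import (
    AllelePool,
    EscapeParams,
    RoundParams,
    enrich_trajectory,
    escape_probability,
)
from .offtarget import SearchParams, enumerate_offtargets, write_candidates_tsv
from .quant import QuantConfig, quantify_reads
from .seqcore import (
    Deletion,
    EFFECTOR_PRESETS,
    EffectorSpec,
    Insertion,
    NucSequence,
    Substitution,
    write_fasta,
)
from .synth import (
    PlantedGenomeSpec,
    PlantedSite,
    ReadSetSpec,
    generate_planted_genome,
    generate_reads,
    write_fastq,
)

__all__ = ["RunConfig", "StageError", "run_pipeline", "load_config"]

log = logging.getLogger("crispramp")

_SCHEMA: dict[str, Any] = {
    "seed": int,
    "effector": str,
    "genome": {"length": int, "guide": str, "planted": list},
    "search": {"max_mismatches": int, "require_pam": bool, "pam_override": str},
    "design": {"window_halfwidth": int},
    "enrichment": {
        "c": float, "carryover": float, "rounds": int, "rounds_max": int,
        "detection_limit": float, "allow_extra_rounds": bool,
        "escape": {"pi_small": float, "pi_big": float, "pi_seed": float,
                   "pi_distal": float, "s_big": int},
    },
    "reads": {
        "n_reads": int, "mutant_fraction": float, "error_rate": float,
        "mutation": {"type": str, "size": int, "start": (int, str),
                     "position": (int, str), "to": str},
    },
    "quant": {"window_halfwidth": int, "min_read_len_frac": float},
    "amplicon_margin": int,
}


class StageError(RuntimeError):
    def __init__(self, stage: str, msg: str):
        super().__init__(f"[{stage}] {msg}")
        self.stage = stage


def _check_keys(cfg: Mapping, schema: Mapping, path: str = "") -> None:
    for key, val in cfg.items():
        if key not in schema:
            raise ValueError(f"unknown config key {path + key!r}")
        sub = schema[key]
        if isinstance(sub, dict):
            if not isinstance(val, Mapping):
                raise ValueError(f"config key {path + key!r} must be a mapping")
            _check_keys(val, sub, path + key + ".")


@dataclass(frozen=True)
class RunConfig:
    """Validated pipeline configuration (unknown keys rejected)."""

    raw: dict

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        _check_keys(d, _SCHEMA)
        for req in ("seed", "genome"):
            if req not in d:
                raise ValueError(f"missing required config key {req!r}")
        return cls(raw=dict(d))

    def get(self, *path, default=None):
        node: Any = self.raw
        for p in path:
            if not isinstance(node, Mapping) or p not in node:
                return default
            node = node[p]
        return node


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _effector(cfg: RunConfig) -> EffectorSpec:
    name = cfg.get("effector", default="AsCas12a")
    try:
        return EFFECTOR_PRESETS[name]
    except KeyError:
        raise StageError("config", f"unknown effector preset {name!r}")


def _parse_mutation(d: Mapping | None, cut: int, amplicon: NucSequence):
    if d is None:
        d = {"type": "deletion", "size": 3, "start": "cut"}
    t = d.get("type", "deletion")
    if t == "deletion":
        size = int(d.get("size", 3))
        start = d.get("start", "cut")
        start = cut - size // 2 if start == "cut" else int(start)
        return Deletion(start, size)
    if t == "insertion":
        size = int(d.get("size", 1))
        pos = d.get("position", "cut")
        pos = cut if pos == "cut" else int(pos)
        return Insertion(pos, size, "A" * size)
    if t == "substitution":
        pos = d.get("position", "cut")
        pos = cut if pos == "cut" else int(pos)
        return Substitution(pos, amplicon.seq[pos], d.get("to", "G"))
    raise StageError("config", f"unknown mutation type {t!r}")


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute all stages; returns the manifest (also written to disk).

    Stage failures raise :class:`StageError`; outputs produced before the
    failure remain on disk alongside a partial manifest.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"version": __version__, "stages": {}, "hashes": {}}
    (out / "resolved_config.json").write_text(json.dumps(config.raw, indent=2))

    def record(stage: str, *paths: Path) -> None:
        manifest["stages"][stage] = [p.name for p in paths]
        for p in paths:
            manifest["hashes"][p.name] = _sha256(p)
            log.info("stage %s wrote %s (sha256=%s)", stage, p.name,
                     manifest["hashes"][p.name][:12])
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    seed = int(config.get("seed"))
    effector = _effector(config)

    # --- stage 1: synthetic reference with planted sites ------------------
    try:
        planted = tuple(
            PlantedSite(
                n_mismatches=int(p.get("n_mismatches", 0)),
                strand=p.get("strand", "+"),
                pam_valid=bool(p.get("pam_valid", True)),
            )
            for p in config.get("genome", "planted",
                                default=[{"n_mismatches": 0}])
        )
        gspec = PlantedGenomeSpec(
            length=int(config.get("genome", "length", default=3000)),
            guide=config.get("genome", "guide"),
            effector=effector,
            planted=planted,
            seed=seed,
        )
        if gspec.guide is None:
            raise ValueError("genome.guide is required")
        genome, truth = generate_planted_genome(gspec)
        fa = out / "reference.fa"
        write_fasta([genome], fa)
        truth_path = out / "planted_truth.tsv"
        truth.to_csv(truth_path, sep="\t", index=False)
        record("synth_genome", fa, truth_path)
    except StageError:
        raise
    except Exception as e:
        raise StageError("synth_genome", str(e)) from e

    # --- stage 2: off-target prediction -----------------------------------
    try:
        params = SearchParams(
            max_mismatches=int(config.get("search", "max_mismatches", default=3)),
            require_pam=bool(config.get("search", "require_pam", default=True)),
            pam_override=config.get("search", "pam_override"),
        )
        cands = enumerate_offtargets([genome], gspec.guide, effector, params)
        pred_path = out / "predicted_candidates.tsv"
        write_candidates_tsv(cands, effector, pred_path)
        record("predict", pred_path)
        on_targets = [c for c in cands if c.n_mismatches == 0]
        if not on_targets:
            raise ValueError("no on-target site found in the planted reference")
        on_site = on_targets[0].site
    except StageError:
        raise
    except Exception as e:
        raise StageError("predict", str(e)) from e

    # --- stage 3: enrichment-guide design ----------------------------------
    try:
        margin = int(config.get("amplicon_margin", default=60))
        lo = max(0, on_site.start - margin)
        hi = min(len(genome), on_site.end + margin)
        amplicon = NucSequence(id="amplicon", seq=genome.seq[lo:hi])
        amp_site = _shift_site(on_site, -lo, "amplicon")
        locus = EditingLocus.for_nuclease(
            amplicon, amp_site, effector,
            window_halfwidth=int(config.get("design", "window_halfwidth", default=3)),
        )
        guides = design_indel_enrichment_guide(locus, effector)
        guide = guides[0]
        dg = pd.DataFrame(
            [
                dict(start=g.site.start + 1, end=g.site.end, strand=g.site.strand,
                     protospacer=g.site.protospacer_seq, pam=g.site.pam_seq,
                     rationale=g.rationale,
                     disrupted_positions=";".join(map(str, g.disrupted_positions)))
                for g in guides
            ]
        )
        design_path = out / "enrichment_guides.tsv"
        dg.to_csv(design_path, sep="\t", index=False)
        amp_path = out / "amplicon.fa"
        write_fasta([amplicon], amp_path)
        record("design", design_path, amp_path)
    except StageError:
        raise
    except Exception as e:
        raise StageError("design", str(e)) from e

    # --- stage 4: enrichment simulation ------------------------------------
    try:
        rounds = int(config.get("enrichment", "rounds", default=3))
        rparams = RoundParams(
            c=float(config.get("enrichment", "c", default=0.9)),
            carryover=float(config.get("enrichment", "carryover", default=0.02)),
            rounds_max=int(config.get("enrichment", "rounds_max", default=3)),
            detection_limit=float(
                config.get("enrichment", "detection_limit", default=0.5)
            ),
        )
        allow_extra = bool(config.get("enrichment", "allow_extra_rounds",
                                      default=False))
        if rounds > rparams.rounds_max:
            log.warning(
                "rounds=%d exceeds the %d-round cap (error accumulation across "
                "repeated amplification); %s",
                rounds, rparams.rounds_max,
                "running anyway (allow_extra_rounds)" if allow_extra
                else "refusing to run",
            )
        esc_cfg = config.get("enrichment", "escape", default={}) or {}
        esc = EscapeParams(**esc_cfg)
        cut = amp_site.cut_position(effector)
        mutation = _parse_mutation(config.get("reads", "mutation"), cut, amplicon)
        pi = escape_probability(mutation, guide, effector, esc)
        m0 = float(config.get("reads", "mutant_fraction", default=0.05))
        pool = AllelePool.two_class(m0, escape=pi, mutation=mutation)
        traj = enrich_trajectory(pool, rparams, rounds,
                                 allow_extra_rounds=allow_extra)
        sim = pd.DataFrame(
            dict(
                round=range(rounds + 1),
                mutant_fraction_model=traj.mutant_fractions,
                fold_model=traj.fold,
                detected_model=[
                    100.0 * m >= rparams.detection_limit
                    for m in traj.mutant_fractions
                ],
            )
        )
        sim_path = out / "simulated_trajectory.tsv"
        sim.to_csv(sim_path, sep="\t", index=False)
        record("simulate", sim_path)
    except StageError:
        raise
    except Exception as e:
        raise StageError("simulate", str(e)) from e

    # --- stage 5: per-round synthetic reads + quantification ---------------
    try:
        n_reads = int(config.get("reads", "n_reads", default=1000))
        error_rate = float(config.get("reads", "error_rate", default=0.0))
        qcfg = QuantConfig(
            window_halfwidth=int(config.get("quant", "window_halfwidth", default=3)),
            min_read_len_frac=float(
                config.get("quant", "min_read_len_frac", default=0.8)
            ),
        )
        rows = []
        for k, m in enumerate(traj.mutant_fractions):
            spec = ReadSetSpec(
                amplicon=amplicon,
                alleles=(("mutant", mutation, float(m)),),
                n_reads=n_reads,
                error_rate=error_rate,
                seed=seed + 1000 + k,
            )
            records, _ = generate_reads(spec)
            fq = out / f"reads_round{k}.fastq"
            write_fastq(records, fq)
            res = quantify_reads(((r, s) for r, s, _ in records), amplicon, cut, qcfg)
            rows.append(
                dict(round=k, n_total=res.n_total, n_indel=res.n_indel,
                     n_discarded=res.n_discarded,
                     indel_pct_measured=res.indel_frequency)
            )
        meas = pd.DataFrame(rows)
        base = meas.loc[0, "indel_pct_measured"]
        meas["fold_measured"] = (
            meas["indel_pct_measured"] / base if base > 0 else float("nan")
        )
        meas["detected"] = meas["indel_pct_measured"] >= rparams.detection_limit
        quant_path = out / "quantified_rounds.tsv"
        meas.to_csv(quant_path, sep="\t", index=False)
        record("quantify", quant_path)
    except StageError:
        raise
    except Exception as e:
        raise StageError("quantify", str(e)) from e

    # --- stage 6: report ----------------------------------------------------
    try:
        report = meas.merge(sim, on="round")
        # column naming labels model-dependent quantities explicitly
        report_path = out / "report.tsv"
        report.to_csv(report_path, sep="\t", index=False)
        record("report", report_path)
    except Exception as e:
        raise StageError("report", str(e)) from e

    return manifest


def _shift_site(site, delta: int, new_ref_id: str):
    from dataclasses import replace

    return replace(site, ref_id=new_ref_id, start=site.start + delta,
                   end=site.end + delta)
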