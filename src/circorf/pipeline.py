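"""End-to-end orchestration: simulate -> annotate -> quant -> screen ->
coding -> design, with config validation and a machine-readable run report.

The report reproduces the discovery funnel (total -> expression-pass ->
length -> junction-ORF -> ORF-position -> IRES -> final candidates) and the
category summary, echoes every threshold used by any stage, and records
sha256 digests of all data outputs so reruns can be compared byte-for-byte.
Stage timings are kept out of the digested report so reruns are comparable.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import pandas as pd
import yaml
from Bio.Seq import Seq

from . import annotate as ann
from . import coding as cod
from . import design as dsn
from . import quant as qnt
from . import screen as scr
from . import simulate as sim
from .errors import CircOrfError, ConfigurationError
from .genome import GenomeBundle

__all__ = ["RunReport", "validate_config", "run_pipeline", "default_config"]


_SCHEMA: dict[str, dict[str, object]] = {
    "seed": 1,
    "simulate": {
        "n_contigs": 2, "contig_length": 80_000, "n_genes": 40,
        "exons_per_gene": [1, 4], "n_circs": 100, "n_coding": 6,
        "n_up_noncoding": 4, "category_mix": dict(sim.DEFAULT_MIX),
        "n_pairs": 5, "planted_fc": 6.0, "noncoding_up_pairs": 3,
        "nb_dispersion": 0.05, "depth": 100.0, "read_length": 50,
        "anchor": 10, "linear_ratio_range": [0.01, 0.06],
        "analog_exon_length": 959,
    },
    "quant": {"anchor": 10, "rnase_threshold": 0.5},
    "screen": {
        "fc": 2.0, "alpha": 0.05, "pseudocount": 0.5,
        "recurrence_k": 3, "recurrence_fc": 2.0, "bh": False,
    },
    "coding": {
        "min_len": 200, "max_len": 3000, "min_aa": 50, "start_window": 0.5,
        "max_cycles": 3, "ires_window": 150, "ires_step": 10,
        "ires_threshold": 0.7, "ires_tail_nt": 30,
    },
    "design": {
        "tag": dsn.FLAG_3X_NT, "min_overhang": 4, "max_missed": 2,
        "amplicon_min": 80, "amplicon_max": 200, "primer_min": 18,
        "primer_max": 24, "gc_min": 0.4, "gc_max": 0.6, "promoter_nt": 300,
    },
}


def default_config() -> dict:
    return json.loads(json.dumps(_SCHEMA))  # deep copy


def _check_type(key: str, value, default) -> object:
    if isinstance(default, bool):
        if not isinstance(value, bool):
            raise ConfigurationError(f"config key {key}: expected bool, got {type(value).__name__}")
        return value
    if isinstance(default, int) and not isinstance(default, bool):
        if isinstance(value, bool) or not isinstance(value, int):
            raise ConfigurationError(f"config key {key}: expected int, got {type(value).__name__}")
        return value
    if isinstance(default, float):
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise ConfigurationError(f"config key {key}: expected number, got {type(value).__name__}")
        return float(value)
    if isinstance(default, str):
        if not isinstance(value, str):
            raise ConfigurationError(f"config key {key}: expected str, got {type(value).__name__}")
        return value
    if isinstance(default, list):
        if not isinstance(value, (list, tuple)) or len(value) != len(default):
            raise ConfigurationError(f"config key {key}: expected list of {len(default)}")
        return [_check_type(f"{key}[{i}]", v, d) for i, (v, d) in enumerate(zip(value, default))]
    if isinstance(default, dict):
        if not isinstance(value, dict):
            raise ConfigurationError(f"config key {key}: expected mapping")
        out = dict(default)
        for k, v in value.items():
            if k not in default:
                raise ConfigurationError(f"unknown config key {key}.{k}")
            out[k] = _check_type(f"{key}.{k}", v, default[k])
        return out
    raise ConfigurationError(f"config key {key}: unsupported type")


def validate_config(source: str | Path | dict | None = None) -> dict:
    """Normalize a YAML config (or dict): fill defaults, reject unknown keys,
    type-check every value, and pre-validate the simulation block so schema
    errors surface before any stage runs."""
    if source is None:
        raw: dict = {}
    elif isinstance(source, dict):
        raw = source
    else:
        raw = yaml.safe_load(Path(source).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config root must be a mapping")
    cfg = dict(default_config())
    for k, v in raw.items():
        if k not in _SCHEMA:
            raise ConfigurationError(f"unknown config key {k}")
        cfg[k] = _check_type(k, v, _SCHEMA[k])
    _sim_config(cfg).validate()
    return cfg


def _sim_config(cfg: dict) -> sim.SimConfig:
    s = dict(cfg["simulate"])
    s["exons_per_gene"] = tuple(s["exons_per_gene"])
    s["linear_ratio_range"] = tuple(s["linear_ratio_range"])
    return sim.SimConfig(seed=cfg["seed"], **s)


@dataclass
class RunReport:
    """Funnel counts, category summary, digests, and the full config echo."""

    outdir: Path
    funnel: dict[str, int]
    category_summary: dict
    final_candidates: list[str]
    digests: dict[str, str] = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    timings: dict[str, float] = field(default_factory=dict)

    def to_rows(self) -> list[tuple[str, str]]:
        rows: list[tuple[str, str]] = []
        for k, v in self.funnel.items():
            rows.append((f"funnel.{k}", str(v)))
        for k, v in self.category_summary.get("counts", {}).items():
            rows.append((f"category.count.{k}", str(v)))
        for k, v in self.category_summary.get("percent", {}).items():
            rows.append((f"category.percent.{k}", str(v)))
        rows.append(("final_candidates", ",".join(self.final_candidates)))

        def flat(prefix: str, d: dict):
            for k, v in d.items():
                if isinstance(v, dict):
                    flat(f"{prefix}.{k}", v)
                else:
                    rows.append((f"config.{prefix}.{k}".replace("config..", "config."), str(v)))

        flat("", self.config)
        for k, v in sorted(self.digests.items()):
            rows.append((f"digest.{k}", v))
        return rows

    def write(self, tsv: Path, txt: Path) -> None:
        pd.DataFrame(self.to_rows(), columns=["key", "value"]).to_csv(tsv, sep="\t", index=False)
        lines = ["circorf run report", "==================", ""]
        lines.append("Discovery funnel (non-increasing):")
        for k, v in self.funnel.items():
            lines.append(f"  {k:>14}: {v}")
        lines.append("")
        lines.append("Category summary:")
        for k in ann.CATEGORIES:
            c = self.category_summary.get("counts", {}).get(k, 0)
            p = self.category_summary.get("percent", {}).get(k, 0)
            lines.append(f"  {k:>18}: {c:4d} ({p}%)")
        lines.append("")
        lines.append(f"Final candidates: {', '.join(self.final_candidates) or '(none)'}")
        lines.append("")
        lines.append("Stage timings (s): " + ", ".join(f"{k}={v:.2f}" for k, v in self.timings.items()))
        txt.write_text("\n".join(lines) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _parent_protein(genome: GenomeBundle, gene) -> str | None:
    off = genome.cds_offset(gene)
    if off is None:
        return None
    cds = genome.transcript_seq(gene)[off:]
    cds = cds[: len(cds) // 3 * 3]
    return str(Seq(cds).translate(to_stop=True))


def run_pipeline(config: dict | str | Path | None, outdir: str | Path) -> RunReport:
    """Run every stage under one run directory; deterministic under seed.

    Layout: genome/, catalog/, quant/, screen/, coding/, design/, report/.
    Stage failures raise with the stage name; partial outputs are retained.
    """
    cfg = validate_config(config)
    out = Path(outdir)
    for sub in ("genome", "catalog", "quant", "screen", "coding", "design", "report"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    simcfg = _sim_config(cfg)
    timings: dict[str, float] = {}

    def stage(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, exc_type, exc, tb):
                timings[name] = time.perf_counter() - self.t0
                if exc is not None and isinstance(exc, CircOrfError):
                    raise CircOrfError(f"stage {name}: {exc}") from exc
                return False

        return _T()

    with stage("simulate"):
        genome = sim.generate_genome(simcfg)
        genome.write_fasta(out / "genome" / "genome.fa")
        genome.write_gff3(out / "genome" / "annotation.gff3")
        truth, bsjs = sim.plant_circrnas(genome, simcfg)
        ann.write_bsj_bed(bsjs, out / "catalog" / "bsj.bed")
        sim.write_truth(truth, out / "catalog" / "truth.tsv")
        circ_cm, lin_cm = sim.simulate_counts(truth, simcfg)
        circ_cm.write(out / "quant" / "circ_counts.tsv")
        lin_cm.write(out / "quant" / "linear_counts.tsv")
        circ_cm.design.to_csv(out / "quant" / "design.tsv", sep="\t", index=False)
        untreated, treated = sim.simulate_junction_reads(truth, simcfg)
        sim.write_fastq(untreated, out / "quant" / "reads_untreated.fastq")
        sim.write_fastq(treated, out / "quant" / "reads_treated.fastq")

    with stage("annotate"):
        genome2 = GenomeBundle.read(out / "genome" / "genome.fa", out / "genome" / "annotation.gff3")
        recs = ann.read_bsj_bed(out / "catalog" / "bsj.bed")
        events = [ann.reconstruct_sequence(r, genome2) for r in recs]
        ann.write_catalog(events, out / "catalog" / "catalog.tsv", out / "catalog" / "circs.fa")
        summary = ann.summarize_catalog(events)

    with stage("quant"):
        qcfg = cfg["quant"]
        bsj_counts = qnt.count_bsj_reads(
            out / "quant" / "reads_untreated.fastq", events, anchor=qcfg["anchor"]
        )
        bsj_counts_trt = qnt.count_bsj_reads(
            out / "quant" / "reads_treated.fastq", events, anchor=qcfg["anchor"]
        )
        bsj_counts.to_frame().join(bsj_counts_trt.rename("bsj_reads_treated")).to_csv(
            out / "quant" / "bsj_read_counts.tsv", sep="\t", index_label="circ_id"
        )
        rnase = qnt.rnase_r_resistance(bsj_counts, bsj_counts_trt, threshold=qcfg["rnase_threshold"])
        rnase.to_csv(out / "quant" / "rnase_r.tsv", sep="\t", index_label="circ_id", na_rep="NA")
        tpm = circ_cm.tpm
        tpm.to_csv(out / "quant" / "circ_tpm.tsv", sep="\t", index_label="circ_id")
        # circ/linear ratio on a shared denominator (joint normalization), so
        # per-feature ratios reflect length-normalized abundance directly
        lin_counts = lin_cm.counts.copy()
        lin_counts.index = ["lin:" + i for i in lin_counts.index]
        joint_counts = pd.concat([circ_cm.counts.loc[lin_cm.counts.index], lin_counts])
        joint_len = pd.concat(
            [circ_cm.lengths.loc[lin_cm.counts.index],
             lin_cm.lengths.rename(lambda i: "lin:" + i)]
        )
        joint_tpm = qnt.tpm_normalize(joint_counts, joint_len)
        ratio = qnt.circ_linear_ratio(
            joint_tpm.loc[lin_cm.counts.index],
            joint_tpm.loc[["lin:" + i for i in lin_cm.counts.index]].set_axis(
                lin_cm.counts.index
            ),
        )
        ratio.to_csv(out / "quant" / "circ_linear_ratio.tsv", sep="\t",
                     index_label="circ_id", na_rep="NA")

    with stage("screen"):
        scfg = cfg["screen"]
        de_table = scr.de_test(
            tpm, circ_cm.design, fc_threshold=scfg["fc"], alpha=scfg["alpha"],
            pseudocount=scfg["pseudocount"], recurrence_k=scfg["recurrence_k"],
            recurrence_fc=scfg["recurrence_fc"], bh=scfg["bh"],
        )
        de_table.to_csv(out / "screen" / "de_table.tsv", sep="\t", index_label="circ_id")

    with stage("coding"):
        ccfg = cfg["coding"]
        params = cod.CodingParams(**{f.name: ccfg[f.name] for f in dc_fields(cod.CodingParams)})
        orfs = {
            ev.circ_id: cod.find_circular_orfs(ev, max_cycles=params.max_cycles)
            for ev in events
        }
        ires = {
            ev.circ_id: cod.scan_ires(
                ev, window=params.ires_window, step=params.ires_step,
                threshold=params.ires_threshold,
            )
            for ev in events
        }
        orf_rows = [
            {
                "circ_id": o.circ_id, "start": o.start, "frame": o.frame,
                "nt_length": o.nt_length, "aa_length": o.aa_length,
                "spans_junction": o.spans_junction, "rolling_circle": o.rolling_circle,
                "cycles_crossed": o.cycles_crossed, "protein": o.protein,
            }
            for olist in orfs.values()
            for o in olist
        ]
        pd.DataFrame(orf_rows).to_csv(out / "coding" / "orfs.tsv", sep="\t", index=False)
        ires_rows = [
            {"circ_id": h.circ_id, "start": h.start, "end": h.end, "score": round(h.score, 4)}
            for hlist in ires.values()
            for h in hlist
        ]
        pd.DataFrame(ires_rows).to_csv(out / "coding" / "ires.tsv", sep="\t", index=False)
        candidates = cod.rank_candidates(events, de_table, orfs, ires, params)
        cand_rows = []
        for c in candidates:
            row = {"circ_id": c.circ_id, "rank": c.rank if c.rank else "NA",
                   "passes": c.passes}
            row.update({f"filter_{k}": v for k, v in c.filters.items()})
            row["orf_aa"] = c.orf.aa_length if c.orf else "NA"
            row["orf_start"] = c.orf.start if c.orf else "NA"
            row["ires"] = f"{c.ires.start}-{c.ires.end}" if c.ires else "NA"
            cand_rows.append(row)
        pd.DataFrame(cand_rows).to_csv(out / "coding" / "candidates.tsv", sep="\t", index=False)

    with stage("design"):
        dcfg = cfg["design"]
        truth_by_id = {t.circ_id: t for t in truth}
        ev_by_id = {ev.circ_id: ev for ev in events}
        construct_fa, primer_rows, sirna_rows, pep_rows, tcf_rows = [], [], [], [], []
        for c in candidates:
            if not c.passes or c.orf is None:
                continue
            ev = ev_by_id[c.circ_id]
            tagged = dsn.tag_orf(ev, c.orf, tag_nt=dcfg["tag"])
            mutant = dsn.mutate_start(ev, c.orf)
            construct_fa.append((f"{c.circ_id}|tagged", tagged.sequence))
            construct_fa.append((f"{c.circ_id}|start_mutant", mutant.sequence))
            pair = dsn.design_divergent_primers(
                ev, primer_min=dcfg["primer_min"], primer_max=dcfg["primer_max"],
                gc_min=dcfg["gc_min"], gc_max=dcfg["gc_max"],
                amplicon_min=dcfg["amplicon_min"], amplicon_max=dcfg["amplicon_max"],
            )
            primer_rows.append(
                {"circ_id": c.circ_id, "forward": pair.forward, "reverse": pair.reverse,
                 "orientation": pair.orientation, "amplicon_length": pair.amplicon_length}
            )
            t = truth_by_id.get(c.circ_id)
            L = ev.length
            doubled = ev.sequence * 2
            for k in range(3):
                sirna = doubled[L - 10 + k : L + 9 + k]
                chk = dsn.check_sirna_junction(
                    sirna, ev, linear_transcript=t.linear_seq if t else None,
                    min_overhang=dcfg["min_overhang"],
                )
                sirna_rows.append({"circ_id": c.circ_id, "sirna": sirna, **chk})
            if t is not None and t.host_gene is not None:
                gene = genome2.gene(t.host_gene)
                parent = _parent_protein(genome2, gene)
                if parent:
                    pe = dsn.junction_peptide(c.orf.protein, parent, max_missed=dcfg["max_missed"])
                    pep_rows.append(
                        {"circ_id": c.circ_id,
                         "divergence_positions": ",".join(map(str, pe.divergence_positions)),
                         "novel_suffix": pe.novel_suffix,
                         "distinguishing_peptides": ",".join(pe.distinguishing)}
                    )
                pn = dcfg["promoter_nt"]
                contig = genome2.contigs[gene.contig]
                if gene.strand == "+":
                    prom = contig[max(0, gene.start - pn) : gene.start]
                else:
                    from .genome import revcomp as _rc

                    prom = _rc(contig[gene.end : gene.end + pn])
                for pos, strand_, m in dsn.scan_tcf_sites(prom):
                    tcf_rows.append({"circ_id": c.circ_id, "gene": gene.gene_id,
                                     "position": pos, "strand": strand_, "site": m})
        with open(out / "design" / "constructs.fa", "w") as fh:
            for name, s in construct_fa:
                fh.write(f">{name}\n{s}\n")
        pd.DataFrame(primer_rows).to_csv(out / "design" / "primers.tsv", sep="\t", index=False)
        pd.DataFrame(sirna_rows).to_csv(out / "design" / "sirna.tsv", sep="\t", index=False)
        pd.DataFrame(pep_rows).to_csv(out / "design" / "peptides.tsv", sep="\t", index=False)
        pd.DataFrame(tcf_rows).to_csv(out / "design" / "tcf_hits.tsv", sep="\t", index=False)

    with stage("report"):
        cum = {"total": len(events)}
        keys = ["de", "length", "orf", "orf_position", "ires"]
        passing = {c.circ_id: c.filters for c in candidates}
        alive = set(passing)
        for k in keys:
            alive = {cid for cid in alive if passing[cid][k]}
            cum[k] = len(alive)
        final = [c.circ_id for c in candidates if c.passes]
        cum["final"] = len(final)
        digests = {}
        for p in sorted(out.rglob("*")):
            if p.is_file() and p.parent.name != "report":
                digests[str(p.relative_to(out))] = _sha256(p)
        report = RunReport(
            outdir=out, funnel=cum, category_summary=summary,
            final_candidates=sorted(final), digests=digests, config=cfg,
            timings=timings,
        )
        report.write(out / "report" / "report.tsv", out / "report" / "report.txt")
    return report
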