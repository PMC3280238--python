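"""End-to-end orchestration with one config, fixed seeds and a manifest.

Stage order: simulate -> est -> annotate -> mass -> align -> mptree ->
subfamilies.  A single master seed deterministically derives per-stage
seeds, every output file is checksummed into ``manifest.json``, and a
stage failure aborts with the failing stage named (partial outputs are
kept on disk).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import align, est, masscalc, parsimony, precursor, subfamily, synthdata
from .errors import NatxError, PipelineError

log = logging.getLogger("natx.pipeline")

CONFIG_SCHEMA_VERSION = "1"

__all__ = ["PipelineConfig", "run_pipeline", "CONFIG_SCHEMA_VERSION"]


@dataclass
class PipelineConfig:
    """All stage parameters plus toggles; round-trips through YAML."""

    out_dir: str = "natx_run"
    seed: int = 1

    # synthetic family
    n_subfamilies: int = 4
    taxa_per_subfamily: int = 3
    scaffold_len: int = 65
    n_cys: int = 8
    sub_rate: float = 0.15

    # reads
    n_reads_per_cds: int = 10
    read_len: int = 150
    read_error_rate: float = 0.01
    vector_fraction: float = 0.2

    # est stage
    trim_window: int = 100
    trim_min_q: int = 20
    vector_min_match: int = 15
    overlap_min: int = 100
    overlap_identity: float = 95.0

    # annotation / mass
    cds_fasta: str = ""  # external CDS FASTA overriding the simulated one
    mass_tolerance_da: float = 1.5

    # alignment
    gap_open: float = 10.0
    gap_extend: float = 0.5
    matrix_name: str = "BLOSUM62"
    user_alignment: str = ""

    # parsimony
    bootstrap_reps: int = 100
    n_starts: int = 10
    cni_level: int = 2
    consensus_cutoff: float = 50.0

    # subfamilies
    min_support: float = 50.0
    consensus_threshold: float = 0.5

    # stage toggles
    run_est: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seed(master: int, stage: str) -> int:
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big")


def run_pipeline(config: PipelineConfig) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "config_schema_version": CONFIG_SCHEMA_VERSION,
        "mass_table_version": masscalc.MASS_TABLE_VERSION,
        "stages": {},
    }
    outputs: dict[str, Path] = {}
    stage = "setup"

    def record(stage_name: str, files: dict, counts: dict, t0: float) -> None:
        manifest["stages"][stage_name] = {
            "wall_seconds": round(time.monotonic() - t0, 3),
            "counts": counts,
            "files": {k: str(p.relative_to(out)) for k, p in files.items()},
        }
        outputs.update(files)
        log.info("stage %s done: %s", stage_name, counts)

    try:
        # ------------------------------------------------------ simulate
        stage = "simulate"
        t0 = time.monotonic()
        truth = synthdata.generate_truth_bundle(
            n_subfamilies=config.n_subfamilies,
            taxa_per_subfamily=config.taxa_per_subfamily,
            scaffold_len=config.scaffold_len,
            n_cys=config.n_cys,
            sub_rate=config.sub_rate,
            seed=_stage_seed(config.seed, "simulate"),
        )
        files = {
            "true_tree": out / "true_tree.nwk",
            "matures": out / "true_matures.fa",
            "cds": out / "cds.fa",
            "truth_table": out / "truth.tsv",
            "reads": out / "reads.fq",
        }
        truth.true_tree.write(files["true_tree"])
        align.write_fasta(truth.matures, files["matures"])
        align.write_fasta({p.id: p.cds for p in truth.true_precursors}, files["cds"])
        pd.DataFrame([
            {"taxon": p.id,
             "subfamily": truth.true_subfamily_of.get(p.id, 0),
             "signal_len": truth.signal_lens[p.id],
             "motif": truth.motifs[p.id],
             "amidated": p.amidated}
            for p in truth.true_precursors
        ]).to_csv(files["truth_table"], sep="\t", index=False)
        vector = synthdata.mock_vector()
        all_reads = []
        for p in truth.true_precursors:
            all_reads.extend(synthdata.fragment_to_ests(
                p.cds, config.n_reads_per_cds, config.read_len,
                error_rate=config.read_error_rate, vector=vector,
                seed=_stage_seed(config.seed, f"reads:{p.id}"),
                vector_fraction=config.vector_fraction,
                id_prefix=f"{p.id}_r"))
        est.write_fastq(all_reads, files["reads"])
        record(stage, files, {"taxa": len(truth.true_precursors),
                              "reads": len(all_reads)}, t0)

        # ----------------------------------------------------------- est
        if config.run_est:
            stage = "est"
            t0 = time.monotonic()
            reads = est.read_fastq(files["reads"])
            kept, rejected = [], 0
            for r in reads:
                tr = est.trim_quality(r, window=config.trim_window,
                                      min_q=config.trim_min_q)
                if tr is None:
                    rejected += 1
                    continue
                kept.append(est.mask_vector(tr, vector,
                                            min_match=config.vector_min_match))
            contig_set = est.cluster_ests(
                kept, min_overlap=config.overlap_min,
                min_identical_per_100=config.overlap_identity)
            files = {
                "contigs": out / "contigs.fa",
                "membership": out / "est_membership.tsv",
            }
            align.write_fasta(
                {f"contig{k + 1:03d}": c.consensus
                 for k, c in enumerate(contig_set.contigs)}, files["contigs"])
            rows = [{"read": rid, "assignment": f"contig{k + 1:03d}"}
                    for k, c in enumerate(contig_set.contigs) for rid in c.members]
            rows += [{"read": rid, "assignment": "singlet"}
                     for rid in contig_set.singlets]
            pd.DataFrame(rows).to_csv(files["membership"], sep="\t", index=False)
            record(stage, files, {"reads_in": len(reads), "rejected": rejected,
                                  "contigs": len(contig_set.contigs),
                                  "singlets": len(contig_set.singlets)}, t0)

        # ------------------------------------------------------ annotate
        stage = "annotate"
        t0 = time.monotonic()
        cds_map = align.read_fasta(config.cds_fasta or out / "cds.fa")
        refs = truth.matures  # reference mature N-termini for auto cleavage
        records, matures = [], {}
        annotated_rows = []
        for pid, cds in cds_map.items():
            rec, mat = precursor.annotate_cds(pid, cds, reference_matures=refs)
            records.append(rec)
            matures[pid] = mat
            annotated_rows.append({
                "id": pid,
                "signal_start": rec.signal[0], "signal_end": rec.signal[1],
                "mature_start": rec.mature[0], "mature_end": rec.mature[1],
                "motif_removed": rec.cterm_pro_seq,
                "amidated": rec.amidated,
                "n_cys": mat.n_cys,
            })
        files = {
            "mature_fa": out / "matures.fa",
            "annotation": out / "annotation.tsv",
        }
        align.write_fasta({m.id: m.seq for m in matures.values()}, files["mature_fa"])
        pd.DataFrame(annotated_rows).to_csv(files["annotation"], sep="\t", index=False)
        record(stage, files, {"precursors": len(records)}, t0)

        # ---------------------------------------------------------- mass
        stage = "mass"
        t0 = time.monotonic()
        results = [masscalc.mass_result(m.id, m.seq, m.n_disulfides, m.amidated)
                   for m in matures.values()]
        # a noisy synthetic measurement table exercises reconciliation
        rng = np.random.default_rng(_stage_seed(config.seed, "mass"))
        exp = [(f"peak{k + 1:02d}", r.average_da + float(rng.normal(0, 0.3)))
               for k, r in enumerate(results) if rng.random() < 0.7]
        recon = masscalc.reconcile(
            [(r.id, r.average_da) for r in results], exp,
            tolerance_da=config.mass_tolerance_da)
        files = {"masses": out / "masses.tsv",
                 "reconciliation": out / "mass_reconciliation.tsv"}
        pd.DataFrame([
            {"id": r.id, "average_da": round(r.average_da, 1),
             "monoisotopic_da": round(r.monoisotopic_da, 1),
             "n_disulfides": r.n_disulfides, "amidated": r.amidated}
            for r in results
        ]).to_csv(files["masses"], sep="\t", index=False)
        recon.to_frame().to_csv(files["reconciliation"], sep="\t", index=False)
        record(stage, files, {"peptides": len(results),
                              "matched": len(recon.pairs)}, t0)

        # --------------------------------------------------------- align
        stage = "align"
        t0 = time.monotonic()
        seqs = {m.id: m.seq for m in matures.values()}
        seqs[synthdata.OUTGROUP_LABEL] = truth.matures[synthdata.OUTGROUP_LABEL]
        if config.user_alignment:
            msa = align.Msa.read(config.user_alignment)
        else:
            msa = align.progressive_msa(
                seqs, gap_open=config.gap_open, gap_extend=config.gap_extend,
                matrix_name=config.matrix_name)
        matrix = align.complete_deletion(msa)
        files = {"alignment": out / "matures.aln", "matrix": out / "matrix.phy"}
        msa.write_clustal(files["alignment"])
        matrix.write_phylip(files["matrix"])
        record(stage, files, {"taxa": len(msa),
                              "columns": msa.n_columns,
                              "kept_positions": matrix.n_positions}, t0)

        # -------------------------------------------------------- mptree
        stage = "mptree"
        t0 = time.monotonic()
        trees = parsimony.bootstrap(
            matrix, n_reps=config.bootstrap_reps,
            seed=_stage_seed(config.seed, "mptree"),
            n_starts=config.n_starts, level=config.cni_level)
        consensus = parsimony.majority_consensus(
            trees, collapse_below=config.consensus_cutoff)
        rooted = parsimony.root_with_outgroup(consensus, synthdata.OUTGROUP_LABEL)
        files = {"replicates": out / "bootstrap_trees.nwk",
                 "consensus": out / "consensus.nwk"}
        with open(files["replicates"], "w") as fh:
            for t in trees:
                fh.write(t.newick() + "\n")
        rooted.write(files["consensus"])
        record(stage, files, {"replicates": len(trees)}, t0)

        # --------------------------------------------------- subfamilies
        stage = "subfamilies"
        t0 = time.monotonic()
        subs = subfamily.extract_subfamilies(rooted, min_support=config.min_support)
        aligned = msa.as_dict()
        for sf in subs:
            sf.consensus = subfamily.consensus_sequence(
                [aligned[m] for m in sf.members],
                majority_threshold=config.consensus_threshold)
        ranks = {name: k + 1 for k, name in enumerate(sorted(seqs))}
        subfamily.assign_nomenclature(subs, ranks)
        table = subfamily.report(subs, seqs, recon)
        files = {"subfamilies": out / "subfamilies.tsv",
                 "consensus_fa": out / "subfamily_consensus.fa"}
        table.to_csv(files["subfamilies"], sep="\t", index=False)
        align.write_fasta({f"NaTx{sf.index}": sf.consensus for sf in subs},
                          files["consensus_fa"])
        record(stage, files, {"subfamilies": len(subs)}, t0)

    except NatxError as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    manifest["checksums"] = {str(p.relative_to(out)): _sha256(p)
                             for p in sorted(outputs.values())}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
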