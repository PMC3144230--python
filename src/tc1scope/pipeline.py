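"""End-to-end orchestration: simulate -> family characterization -> mapping ->
signature statistics, from one validated config, with a consolidated report.

Each stage reads the previous stage's outputs (or configured input files),
writes its products atomically under ``outdir``, and records counts in the run
report; retained + dropped reconciles with the input at every filter.
"""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from . import famchar, io, sigstats, srmap
from ._seq import substream
from .config import normalize_config
from .synthdata import (
    LENGTH_WEIGHTS_24_25,
    LENGTH_WEIGHTS_27_28,
    ElementArchitecture,
    SignatureParams,
    build_consensus_element,
    plant_copies,
    simulate_background_reads,
    simulate_pirna_reads,
    SmallRead,
)

__all__ = ["StageError", "run_pipeline"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _log(msg: str) -> None:
    print(f"[tc1scope] {msg}", file=sys.stderr)


def _background_transcripts(genome: dict[str, str], truth: pd.DataFrame, seed: int, n: int = 2, tlen: int = 2000) -> dict[str, str]:
    """Non-TE 'transcripts' cut from copy-free genome regions, so background
    degradation fragments exact-match the genome like real ones do."""
    rng = substream(seed, 4)
    names = ["ef1a_like", "odc_like", "bg3", "bg4"]
    out: dict[str, str] = {}
    chroms = sorted(genome)
    for i in range(n):
        for _ in range(200):
            chrom = chroms[rng.integers(0, len(chroms))]
            L = len(genome[chrom])
            if L <= tlen:
                continue
            start = int(rng.integers(0, L - tlen))
            occupied = truth[(truth.chrom == chrom) & (truth.start < start + tlen) & (truth.end > start)]
            if len(occupied) == 0:
                out[names[i]] = genome[chrom][start : start + tlen]
                break
        else:
            raise RuntimeError("could not find a copy-free genome window for background transcripts")
    return out


def _append_adapter(reads: list[SmallRead], adapter: str, raw_len: int, seed: int) -> list[SmallRead]:
    """Emit machine-length raw reads: insert followed by the adapter prefix."""
    out = []
    for r in reads:
        tail = adapter * ((raw_len - r.length) // len(adapter) + 1)
        out.append(SmallRead(r.read_id, (r.sequence + tail)[:raw_len]))
    return out


def _stage_simulate(cfg: dict, outdir: Path, report: dict) -> dict:
    seed = cfg["seed"]
    arch = ElementArchitecture(seed=seed, **cfg["element"])
    consensus = build_consensus_element(arch)
    genome, copy_truth = plant_copies(
        genome_len=cfg["genome"]["genome_len"],
        n_chrom=cfg["genome"]["n_chrom"],
        consensus=consensus,
        n_copies=cfg["genome"]["n_copies"],
        sub_rate=cfg["genome"]["sub_rate"],
        n_intact=cfg["genome"]["n_intact"],
        seed=seed,
    )
    weights = LENGTH_WEIGHTS_27_28 if cfg["reads"]["length_preset"] == "27-28" else LENGTH_WEIGHTS_24_25
    params = SignatureParams(
        n_reads=cfg["reads"]["n_reads"],
        antisense_fraction=cfg["reads"]["antisense_fraction"],
        pingpong_fraction=cfg["reads"]["pingpong_fraction"],
        u1_prob=cfg["reads"]["u1_prob"],
        a10_prob=cfg["reads"]["a10_prob"],
        length_weights=weights,
        seed=seed,
    )
    te_reads, te_truth = simulate_pirna_reads(consensus, params)
    transcripts = _background_transcripts(genome, copy_truth, seed)
    bg_reads, bg_truth = simulate_background_reads(transcripts, cfg["reads"]["n_background"], seed=seed)
    reads = te_reads + bg_reads
    truth = pd.concat([te_truth, bg_truth], ignore_index=True)

    raw = reads
    if cfg["reads"]["append_adapter"]:
        raw = _append_adapter(reads, cfg["map"]["adapter"], cfg["reads"]["raw_read_len"], seed)

    io.write_fasta({consensus.id: consensus.sequence}, outdir / "consensus.fasta")
    io.write_fasta(genome, outdir / "genome.fasta")
    io.write_fasta(transcripts, outdir / "transcripts.fasta")
    io.write_tsv(copy_truth, outdir / "copies_truth.tsv")
    io.write_tsv(truth, outdir / "reads_truth.tsv")
    io.write_fastq(raw, outdir / "reads.fastq")
    report["simulate"] = {
        "n_copies": int(len(copy_truth)),
        "n_te_reads": len(te_reads),
        "n_background_reads": len(bg_reads),
        "n_raw_reads": len(raw),
    }
    _log(f"simulate: {len(copy_truth)} copies, {len(raw)} raw reads")
    return {
        "consensus": consensus,
        "genome": genome,
        "transcripts": transcripts,
        "copy_truth": copy_truth,
        "raw_reads": raw,
    }


def _stage_famchar(cfg: dict, outdir: Path, state: dict, report: dict) -> None:
    consensus = state["consensus"]
    genome = state["genome"]
    fc = cfg["famchar"]
    primer = consensus.sequence[: fc["primer_len"]]
    loci = famchar.insilico_pcr(genome, primer, fc["max_amplicon"], fc["max_mismatch"])
    if not loci:
        raise RuntimeError("in-silico PCR extracted no loci")
    oriented: dict[str, str] = {}
    strands: dict[str, str] = {}
    for l in loci:
        name = f"{l.chrom}:{l.interval[0] + 1}-{l.interval[1]}"
        seq, strand = famchar.orient_to_consensus(l.sequence, consensus.sequence)
        oriented[name] = seq
        strands[name] = strand
    matrix = famchar.all_vs_all_identity(oriented)
    clusters = famchar.single_linkage(matrix, fc["threshold"])
    ir = famchar.detect_terminal_inverted_repeats(consensus.sequence, fc["ir_min_len"], fc["ir_min_identity"])
    drs = famchar.detect_direct_repeats(consensus.sequence, ir, fc["dr_min_len"]) if ir else []
    statuses = []
    for name, seq in oriented.items():
        aln = famchar.align_to_consensus(seq, consensus.sequence)
        statuses.append(famchar.classify_orf(seq, consensus.orf_interval, aln, copy_id=name))
    summary = famchar.family_summary(list(oriented.values()), statuses, matrix)

    io.write_fasta(oriented, outdir / "loci.fasta")
    mat = pd.DataFrame(matrix.values, columns=list(matrix.ids))
    mat.insert(0, "id", list(matrix.ids))
    io.write_tsv(mat, outdir / "identity_matrix.tsv")
    io.write_tsv(
        pd.DataFrame(
            [(i + 1, m) for i, c in enumerate(clusters) for m in c],
            columns=["cluster", "member"],
        ),
        outdir / "clusters.tsv",
    )
    io.write_bed(
        [(l.chrom, l.interval[0], l.interval[1], f"copy{i + 1}", 0.0, strands[f"{l.chrom}:{l.interval[0] + 1}-{l.interval[1]}"])
         for i, l in enumerate(loci)],
        outdir / "loci.bed",
    )
    # structure report: 1-based inclusive coordinates
    rows = [
        ("consensus", "ir_left", ir.left[0] + 1, ir.left[1], f"{ir.percent_identity:.2f}"),
        ("consensus", "ir_right", ir.right[0] + 1, ir.right[1], f"{ir.percent_identity:.2f}"),
    ] if ir else []
    for d in drs:
        rows.append(("consensus", "direct_repeat", d.left[0] + 1, d.left[1], str(d.length)))
        rows.append(("consensus", "direct_repeat", d.right[0] + 1, d.right[1], str(d.length)))
    for st in statuses:
        rows.append((st.copy_id, "orf_status", "", "", f"{st.status}:{st.reason}"))
    io.write_tsv(pd.DataFrame(rows, columns=["id", "feature", "start1", "end1", "value"]), outdir / "structure_report.tsv")

    report["famchar"] = {
        "n_loci": len(loci),
        "n_clusters": len(clusters),
        "ir_length": ir.length if ir else None,
        "dr_length": drs[0].length if drs else None,
        "n_intact": summary["n_intact"],
        "mean_length": summary["mean_length"],
        "min_identity": summary["min_identity"],
    }
    _log(f"famchar: {len(loci)} loci, IR {ir.length if ir else '-'} bp, {summary['n_intact']} intact ORFs")


def _stage_map(cfg: dict, outdir: Path, state: dict, report: dict) -> dict:
    consensus = state["consensus"]
    mp = cfg["map"]
    raw = state["raw_reads"]
    kept, dropped = srmap.preprocess_reads(raw, mp["adapter"])
    selected = srmap.select_lengths(kept, mp["min_len"], mp["max_len"])

    refs = {consensus.id: consensus.sequence, **state["transcripts"]}
    genome_refs = {f"genome:{c}": s for c, s in state["genome"].items()} if mp["map_to_genome"] else {}
    hits = srmap.exact_map(selected, {**refs, **genome_refs})
    element_hits = [h for h in hits if h.ref_id == consensus.id]
    other_hits = [h for h in hits if h.ref_id in state["transcripts"]]
    genome_matched = {h.read_id for h in hits if h.ref_id.startswith("genome:")}

    counts, contributions, exclusions = srmap.assign_to_elements(
        element_hits + other_hits,
        family_of_ref={consensus.id: consensus.id},
        other_refs=set(state["transcripts"]),
    )
    norm_total = len(genome_matched) if mp["map_to_genome"] else len(selected)
    counts = srmap.rpm_normalize(counts, max(norm_total, 1))

    io.write_tsv(srmap.hits_to_frame(element_hits + other_hits), outdir / "hits.tsv")
    io.write_tsv(counts.assign(excluded_multifamily=exclusions["multi_family"]), outdir / "element_counts.tsv")
    report["map"] = {
        "n_raw": len(raw),
        "dropped_mis_read": dropped["mis_read"],
        "dropped_too_short": dropped["too_short"],
        "n_preprocessed": len(kept),
        "n_selected": len(selected),
        "n_genome_matched": len(genome_matched) if mp["map_to_genome"] else None,
        "normalization_total": norm_total,
        "exclusions": exclusions,
    }
    _log(f"map: {len(raw)} raw -> {len(kept)} preprocessed -> {len(selected)} selected; "
         f"{int(counts.specific.sum())} element-specific")
    return {
        "selected": selected,
        "element_hits": element_hits,
        "contributions": contributions,
        "counts": counts,
    }


def _stage_signatures(cfg: dict, outdir: Path, state: dict, report: dict) -> None:
    consensus = state["consensus"]
    contributions = state["contributions"]
    element_hits = state["element_hits"]
    selected = {r.read_id: r for r in state["selected"]}
    contrib_ids = set(contributions.read_id)
    contrib_strand = dict(zip(contributions.read_id, contributions.strand))
    hits = [h for h in element_hits if h.read_id in contrib_ids]

    sense_frac, anti_frac = sigstats.strand_composition(contributions) if len(contributions) else (float("nan"),) * 2
    reads = [selected[rid] for rid in sorted(contrib_ids)]
    spectrum = sigstats.length_spectrum(reads)
    sense_reads = [selected[rid] for rid in sorted(contrib_ids) if contrib_strand[rid] == "+"]
    anti_reads = [selected[rid] for rid in sorted(contrib_ids) if contrib_strand[rid] == "-"]
    cov5 = sigstats.coverage_profile(hits, len(consensus), "five_prime_only")
    cova = sigstats.coverage_profile(hits, len(consensus), "all_positions")
    overlap = sigstats.pingpong_overlap_spectrum(hits)

    io.write_tsv(
        pd.DataFrame(sorted(spectrum.counts.items()), columns=["length", "count"]),
        outdir / "length_spectrum.tsv",
    )
    for label, rds in [("sense", sense_reads), ("antisense", anti_reads)]:
        if rds:
            m = sigstats.positional_base_matrix(rds)
            df = m.freq.reset_index()
            df["IC"] = m.information_content
            io.write_tsv(df, outdir / f"base_matrix_{label}.tsv")
    io.write_tsv(
        pd.DataFrame({"position": np.arange(1, len(consensus) + 1), "sense": cov5.sense, "antisense": cov5.antisense}),
        outdir / "coverage_5p.tsv",
    )
    io.write_tsv(
        pd.DataFrame({"position": np.arange(1, len(consensus) + 1), "sense": cova.sense, "antisense": cova.antisense}),
        outdir / "coverage_all.tsv",
    )
    io.write_tsv(
        pd.DataFrame(sorted(overlap.counts.items()), columns=["overlap", "count"]),
        outdir / "overlap_spectrum.tsv",
    )
    db_fraction = None
    if cfg["signatures"]["pirna_db"]:
        db = io.read_fasta(cfg["signatures"]["pirna_db"]).values()
        db_fraction = sigstats.reference_set_overlap(reads, db)
    report["signatures"] = {
        "n_contributing_reads": len(reads),
        "sense_fraction": sense_frac,
        "antisense_fraction": anti_frac,
        "modal_length": spectrum.modal_length if reads else None,
        "fraction_23_30": spectrum.fraction_in(23, 30) if reads else None,
        "modal_overlap": overlap.modal_overlap if hits else None,
        "pirna_db_fraction": db_fraction,
    }
    _log(f"signatures: antisense {anti_frac:.3f}, modal length {report['signatures']['modal_length']}, "
         f"modal overlap {report['signatures']['modal_overlap']}")


def run_pipeline(config: dict, outdir: str | Path, seed: int | None = None) -> dict:
    """Execute the enabled stages in order and return the run report.

    ``config`` is a normalized config mapping (see :func:`tc1scope.config.validate_config`);
    ``seed`` overrides ``config['seed']``. Identical config + seed gives
    byte-identical outputs.
    """
    cfg = normalize_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg["seed"], "config": cfg}
    state: dict = {}

    stages = cfg["stages"]
    try:
        if stages["simulate"]:
            state.update(_stage_simulate(cfg, outdir, report))
        else:
            state["genome"] = io.read_fasta(cfg["inputs"]["genome_fasta"]) if cfg["inputs"]["genome_fasta"] else None
            if cfg["inputs"]["consensus_fasta"]:
                seqs = io.read_fasta(cfg["inputs"]["consensus_fasta"])
                from .famchar import detect_terminal_inverted_repeats  # noqa: F401 (structure recovered downstream)
                cid, cseq = next(iter(seqs.items()))
                state["consensus"] = _consensus_from_fasta(cid, cseq, cfg)
            state["transcripts"] = io.read_fasta(cfg["inputs"]["transcripts_fasta"]) if cfg["inputs"]["transcripts_fasta"] else {}
            state["raw_reads"] = io.read_reads(cfg["inputs"]["reads_fastq"]) if cfg["inputs"]["reads_fastq"] else []
            state["copy_truth"] = pd.DataFrame(columns=["chrom", "start", "end"])
    except Exception as e:
        raise StageError("simulate", e) from e

    for name, fn in [("famchar", _stage_famchar), ("map", _stage_map), ("signatures", _stage_signatures)]:
        if not stages[name]:
            continue
        try:
            result = fn(cfg, outdir, state, report)
            if result:
                state.update(result)
        except Exception as e:
            raise StageError(name, e) from e

    io.write_json(_jsonable(report), outdir / "report.json")
    return report


def _consensus_from_fasta(cid: str, cseq: str, cfg: dict):
    """Reconstruct a consensus annotation from a bare FASTA sequence by
    detecting the IR structure and the longest ORF on the forward strand."""
    from .famchar import detect_terminal_inverted_repeats
    from .synthdata import ElementConsensus
    from ._seq import STOP_CODONS

    ir = detect_terminal_inverted_repeats(cseq, cfg["famchar"]["ir_min_len"], cfg["famchar"]["ir_min_identity"])
    best = (0, 0, 0)  # length, start, end
    for frame in range(3):
        start = None
        for i in range(frame, len(cseq) - 2, 3):
            codon = cseq[i : i + 3]
            if start is None and codon == "ATG":
                start = i
            elif start is not None and codon in STOP_CODONS:
                if i + 3 - start > best[0]:
                    best = (i + 3 - start, start, i + 3)
                start = None
    ir_left = ir.left if ir else (0, 0)
    ir_right = ir.right if ir else (len(cseq), len(cseq))
    return ElementConsensus(
        id=cid, sequence=cseq, ir_left=ir_left, ir_right=ir_right,
        dr_intervals=(), orf_interval=(best[1], best[2]), orf_frame=best[1] % 3, pas_interval=None,
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and obj != obj:
        return None
    return obj
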