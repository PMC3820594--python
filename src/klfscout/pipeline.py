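"""Pipeline orchestration: configuration, staging, manifests.

Stages run in the order synteny -> locus scan -> zinc-finger grammar ->
repeat motif -> evolution, each consuming only the declared outputs of the
previous one.  All randomness flows from a single top-level seed through
named per-stage substreams, so identical inputs and configuration reproduce
identical outputs byte for byte (manifest timestamps aside).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .errors import StageError
from .evolution import (
    EventHistory,
    EventMember,
    anchor_align,
    classify_events,
    nj_tree,
    p_distance,
)
from .io import config_hash, write_locus_models_gff3
from .locus_scan import LocusModel, call_status, has_repeat_similarity, scan_locus_copies
from .records import GenomeRecord
from .repeat_motif import MotifPattern, rank_proteome, repeat_profile
from .synteny import (
    DEFAULT_DOWNSTREAM_ANCHORS,
    DEFAULT_UPSTREAM_ANCHORS,
    GeneTable,
    GenomeLocusResult,
    SyntenyLocus,
    build_presence_matrix,
    combine_status,
    find_anchored_interval,
)
from .zf_grammar import GrammarParams, find_c2h2_domains, signature_of, contact_report

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "GenomeAnalysis", "run_pipeline", "proteome_report"]

_GRAMMAR_KEYS = [f.name for f in dataclasses.fields(GrammarParams)]


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable knobs of the pipeline; round-trips losslessly through YAML."""

    # grammar (keys mirror GrammarParams field names)
    cys_gap_min: int = 2
    cys_gap_max: int = 4
    inner_gap: int = 12
    his_gap: int = 3
    linker_length: int = 7
    allow_terminal_cys_for_his: bool = True
    # repeat motif
    motif_pattern: str = "[YC]x[GASTDNPE][QH]"
    segment_flank: int = 5
    period_target: int = 14
    period_tolerance: int = 4
    min_repeat_hits: int = 5
    # synteny
    upstream_anchors: tuple[str, ...] = DEFAULT_UPSTREAM_ANCHORS
    downstream_anchors: tuple[str, ...] = DEFAULT_DOWNSTREAM_ANCHORS
    max_interval_span: int = 1_000_000
    # locus scan
    max_pair_gap: int = 20_000
    detect_degraded: bool = True
    # evolution
    locality_bp: int = 250_000
    root_member: str = ""
    # reproducibility
    seed: int = 0

    def grammar_params(self) -> GrammarParams:
        return GrammarParams(**{k: getattr(self, k) for k in _GRAMMAR_KEYS})

    def motif(self) -> MotifPattern:
        return MotifPattern.from_string(self.motif_pattern)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["upstream_anchors"] = list(self.upstream_anchors)
        d["downstream_anchors"] = list(self.downstream_anchors)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise StageError("config", f"unknown config keys: {sorted(unknown)}")
        data = dict(data)
        for key in ("upstream_anchors", "downstream_anchors"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        from .io import load_config_dict

        return cls.from_dict(load_config_dict(path))

    def to_file(self, path) -> None:
        from .io import dump_config_dict

        dump_config_dict(self.to_dict(), path)

    def hash(self) -> str:
        return config_hash(self.to_dict())


@dataclass
class RunManifest:
    tool_version: str
    config_hash: str
    input_digests: dict[str, str]
    record_counts: dict[str, int]
    timestamp: str

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


@dataclass
class GenomeAnalysis:
    """Everything the pipeline learned about one genome."""

    genome_id: str
    locus: SyntenyLocus | None
    models: list[tuple[str, LocusModel, str]]  # (model id, model, status)
    result: GenomeLocusResult
    members: list[EventMember]
    events: EventHistory | None = None


def _member_id_for(model: LocusModel, table: GeneTable, fallback: str) -> str:
    """Name a detected model by the annotated gene it overlaps, if any."""
    if not model.segments:
        return fallback
    start = min(s.start for s in model.segments)
    end = max(s.end for s in model.segments)
    for f in table.features:
        if f.chrom == model.chrom and f.start < end and f.end > start:
            return f.gene_id
    return fallback


def analyze_genome(
    genome: GenomeRecord, table: GeneTable, config: PipelineConfig
) -> GenomeAnalysis:
    """Synteny + locus scan + status calling for one genome."""
    params = config.grammar_params()
    locus = find_anchored_interval(
        table, config.upstream_anchors, config.downstream_anchors, config.max_interval_span
    )

    models: list[tuple[str, LocusModel, str]] = []
    members: list[EventMember] = []
    anchor_ids = set(config.upstream_anchors) | set(config.downstream_anchors)
    windows: list[tuple[str, int, int]] = []
    if locus is not None:
        windows.append((locus.chrom, locus.start, locus.end))
    for f in table.features:
        if f.gene_id in anchor_ids:
            continue
        if locus is not None and f.chrom == locus.chrom and f.start >= locus.start and f.end <= locus.end:
            continue  # already covered by the anchored window
        margin = 300
        windows.append((f.chrom, max(f.start - margin, 0), f.end + margin))

    locus_statuses: list[str] = []
    repeat_flag = False
    for w_i, (chrom, start, end) in enumerate(windows):
        dna = genome.chromosomes[chrom][start:end]
        found = scan_locus_copies(
            dna,
            params,
            chrom=chrom,
            offset=start,
            max_pair_gap=config.max_pair_gap,
            detect_degraded=config.detect_degraded,
        )
        in_locus = locus is not None and w_i == 0
        if in_locus and not any(m.n_fingers >= 3 for m in found):
            repeat_flag = has_repeat_similarity(dna, config.motif(), config.min_repeat_hits)
        for k, model in enumerate(found, 1):
            status = call_status(model)
            model_id = _member_id_for(model, table, f"{genome.id}.{chrom}.m{w_i}_{k}")
            models.append((model_id, model, status))
            if in_locus:
                locus_statuses.append(status)
            if model.n_fingers >= 1 and status != "absent":
                zf_seq = "".join(seg.peptide for seg in model.segments)
                feature = None
                for f in table.features:
                    if f.gene_id == model_id:
                        feature = f
                        break
                if feature is None:
                    from .synteny import GeneFeature

                    seg_start = min(s.start for s in model.segments)
                    seg_end = max(s.end for s in model.segments)
                    feature = GeneFeature(model.chrom, seg_start, seg_end, model_id, model.strand)
                member = EventMember(model_id, feature, model.intron_structure, zf_seq)
                existing = next((i for i, m in enumerate(members) if m.id == model_id), None)
                if existing is None:
                    members.append(member)
                elif len(zf_seq) > len(members[existing].zf_sequence):
                    # a gene seen twice keeps its richer model
                    members[existing] = member

    n_copies = sum(
        1 for (mid, m, s) in models if m.n_fingers >= 3 and (locus is None or _inside(m, locus))
    )
    if locus is None:
        status = "absent"
        n_copies = 0
    else:
        status = combine_status(locus_statuses, repeat_flag)
        if status == "absent":
            n_copies = 0
    result = GenomeLocusResult(genome.id, locus is not None, n_copies, status)
    return GenomeAnalysis(genome.id, locus, models, result, members)


def _inside(model: LocusModel, locus: SyntenyLocus) -> bool:
    if not model.segments:
        return False
    start = min(s.start for s in model.segments)
    end = max(s.end for s in model.segments)
    return model.chrom == locus.chrom and start >= locus.start and end <= locus.end


def run_pipeline(
    config: PipelineConfig,
    genomes: list[tuple[GenomeRecord, GeneTable]],
    out_dir,
) -> tuple[pd.DataFrame, list[GenomeAnalysis], RunManifest]:
    """Run all stages over a set of genomes and write the output bundle."""
    if not genomes:
        raise StageError("input", "no genomes provided")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    analyses = []
    for genome, table in genomes:
        try:
            analyses.append(analyze_genome(genome, table, config))
        except StageError:
            raise
        except Exception as exc:  # pragma: no cover - defensive
            raise StageError("locus_scan", f"{genome.id}: {exc}") from exc

    presence = build_presence_matrix([a.result for a in analyses])
    presence.to_csv(out / "presence_matrix.tsv", sep="\t")

    all_models = []
    for a in analyses:
        all_models.extend(a.models)
    write_locus_models_gff3(all_models, out / "gene_models.gff3")

    event_rows = []
    for a in analyses:
        if len(a.members) >= 2:
            root = config.root_member or min(m.id for m in a.members)
            if all(m.id != root for m in a.members):
                root = min(m.id for m in a.members)
            try:
                a.events = classify_events(a.members, config.locality_bp, root)
            except Exception as exc:
                raise StageError("evolution", f"{a.genome_id}: {exc}") from exc
            for e in a.events.events:
                event_rows.append(
                    {
                        "genome_id": a.genome_id,
                        "child": e.child,
                        "parent": e.parent,
                        "mechanism": e.mechanism,
                        "identity": round(e.identity, 4),
                        "distance_bp": e.distance_bp,
                    }
                )
    pd.DataFrame(
        event_rows,
        columns=["genome_id", "child", "parent", "mechanism", "identity", "distance_bp"],
    ).to_csv(out / "events.tsv", sep="\t", index=False)

    manifest = RunManifest(
        tool_version=__version__,
        config_hash=config.hash(),
        input_digests={g.id: _genome_digest(g) for g, _ in genomes},
        record_counts={
            "genomes": len(genomes),
            "models": len(all_models),
            "events": len(event_rows),
        },
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    manifest.write(out / "manifest.json")
    return presence, analyses, manifest


def _genome_digest(genome: GenomeRecord) -> str:
    import hashlib

    h = hashlib.sha256()
    for name in sorted(genome.chromosomes):
        h.update(name.encode())
        h.update(genome.chromosomes[name].encode())
    return h.hexdigest()


def proteome_report(proteins, config: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Zinc-finger signatures and repeat analytics for a proteome.

    Returns (signature table, repeat-density ranking).  Finger coordinates
    are reported 1-based inclusive for readability.
    """
    params = config.grammar_params()
    pattern = config.motif()
    rows = []
    for p in proteins:
        fingers = find_c2h2_domains(p, params)
        sig = signature_of(fingers, len(p), params)
        contact = ""
        if len(fingers) == 3:
            rep = contact_report(p, fingers, params=params)
            contact = f"{rep.n_pass}/{rep.n_checked}"
        prof = repeat_profile(p, pattern, config.segment_flank, config.period_target, config.period_tolerance)
        rows.append(
            {
                "id": p.id,
                "finger_count": sig.finger_count,
                "fingers_1based": ";".join(f"{f.c1 + 1}-{f.h2 + 1}" for f in fingers),
                "cys_gaps": ",".join(map(str, sig.cys_gaps)),
                "label": sig.label.value,
                "contact_pass": contact,
                "n_motif_hits": prof.n_hits,
                "motif_density": round(prof.density, 6),
                "y_fraction": round(prof.y_fraction, 4),
                "n_tandem_runs": len(prof.runs),
            }
        )
    signatures = pd.DataFrame(rows)
    ranking = rank_proteome(list(proteins), pattern)
    return signatures, ranking
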