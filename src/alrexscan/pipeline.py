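"""Configuration-driven pipeline orchestration.

Executes the analysis stages in dependency order on a synthetic (or
user-provided) dataset: simulate -> ingest -> redundancy -> features ->
motif-scan -> null-rank -> enrich, writing TSV/JSON reports plus a run
manifest recording inputs, parameters, seeds and per-stage row counts.
All randomized stages take seeds derived deterministically from one master
seed, so a fixed configuration reproduces byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
import yaml

from . import codons, enrichment, ingest, nullmodels, pssm, redundancy, simulate
from .ingest import LeaderClass

log = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "ingest",
    "redundancy",
    "features",
    "motif-scan",
    "null-rank",
    "enrich",
)


@dataclass
class RunConfig:
    outdir: str = "alrexscan_run"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    profile: str = "test"           # 'test' or 'full' null-model sizes
    # simulate
    n_pos: int = 2594
    n_neg: int = 938
    cds_length: int = 300
    motif_consensus: str = "CGSSGC"
    # redundancy
    min_identity: float = 0.9
    min_overlap: int = 60
    # null ranking
    n_null: int = 1000
    fpr_grid: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7)
    # enrichment
    n_terms: int = 50
    n_resamples: int = 1000
    n_strata: int = 10

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.n_null < 100:
            raise ValueError("n_null must be >= 100")
        if self.profile not in ("test", "full"):
            raise ValueError("profile must be 'test' or 'full'")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        if "fpr_grid" in data:
            data["fpr_grid"] = tuple(data["fpr_grid"])
        return cls(**data)


def _stage_seed(master: int, stage: str) -> int:
    # stable per-stage derived seed, kept below 2^31
    return (master * 1000003 + STAGES.index(stage) * 7919 + 17) % (2**31 - 1)


def run_pipeline(config: RunConfig) -> dict:
    """Run the requested stages in dependency order; returns the manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "stages": {},
    }
    n_null = config.n_null if config.profile == "test" else max(config.n_null, 100000)

    records = None
    ledger = None

    if "simulate" in config.stages:
        scfg = simulate.SyntheticConfig(
            n_pos=config.n_pos,
            n_neg=config.n_neg,
            cds_length=config.cds_length,
            motif_consensus=config.motif_consensus,
            seed=_stage_seed(config.seed, "simulate"),
        )
        records, ledger = simulate.gen_dataset(scfg)
        paths = simulate.write_dataset(records, ledger, scfg, outdir / "data")
        manifest["stages"]["simulate"] = {
            "seed": scfg.seed,
            "n_records": len(records),
            "outputs": {k: str(v) for k, v in paths.items()},
        }

    if "ingest" in config.stages:
        data_dir = outdir / "data"
        fasta = data_dir / "transcripts.fa"
        if not fasta.exists():
            raise FileNotFoundError("ingest stage: missing upstream simulate artifacts")
        parsed = ingest.parse_cds_fasta(fasta)
        annotation = ingest.read_annotation_table(data_dir / "annotation.tsv")
        leader_ids = ingest.read_id_list(next(data_dir.glob("*_ids.txt")))
        records = ingest.build_transcript_records(
            parsed.records, annotation, sscr_ids=leader_ids, mscr_ids=set()
        )
        records, filter_report = ingest.apply_cds_filters(records)
        records = ingest.dedup_splice_variants(
            records, "identical_leader69", seed=_stage_seed(config.seed, "ingest")
        )
        manifest["stages"]["ingest"] = {
            "n_parsed": len(parsed.records),
            "n_rejected": len(parsed.rejected),
            "filters": dataclasses.asdict(filter_report),
            "n_after_dedup": len(records),
        }

    if records is None:
        raise FileNotFoundError("no upstream records; run the simulate/ingest stages")
    labels = {r.transcript_id: r.has_5ui for r in records}
    pos_recs = [r for r in records if not r.has_5ui]
    neg_recs = [r for r in records if r.has_5ui]

    if "redundancy" in config.stages:
        clusters = redundancy.cluster_first99(
            records, min_identity=config.min_identity, min_overlap=config.min_overlap
        )
        records = redundancy.pick_representatives(
            clusters, records, seed=_stage_seed(config.seed, "redundancy")
        )
        redundancy.write_cluster_report(clusters, outdir / "clusters.tsv")
        manifest["stages"]["redundancy"] = {
            "n_clusters": len(clusters),
            "n_representatives": len(records),
        }
        labels = {r.transcript_id: r.has_5ui for r in records}
        pos_recs = [r for r in records if not r.has_5ui]
        neg_recs = [r for r in records if r.has_5ui]

    if "features" in config.stages:
        table = codons.feature_table(records)
        table.to_csv(outdir / "features.tsv", sep="\t", index=False)
        comparisons = {}
        g1 = [codons.codon_feature_vector(r.cds[:69]) for r in pos_recs]
        g2 = [codons.codon_feature_vector(r.cds[:69]) for r in neg_recs]
        if g1 and g2:
            for feat in codons.FEATURES:
                cmp = codons.compare_groups(
                    g1, g2, feat, seed=_stage_seed(config.seed, "features")
                )
                comparisons[feat] = cmp.to_dict()
        (outdir / "feature_comparisons.json").write_text(
            json.dumps(comparisons, indent=2, default=float) + "\n"
        )
        manifest["stages"]["features"] = {
            "n_rows": len(table),
            "comparisons": sorted(comparisons),
        }

    target = None
    hits_by_id: dict = {}
    if "motif-scan" in config.stages:
        background = nullmodels.empirical_background([r.cds for r in records])
        target = pssm.pssm_from_consensus(
            config.motif_consensus, background=background
        )
        max_pos = [pssm.max_window_score(target, r.cds) for r in pos_recs]
        max_neg = [pssm.max_window_score(target, r.cds) for r in neg_recs]
        sel = pssm.select_threshold_tstar(max_pos, max_neg)
        all_hits = []
        for r in records:
            hits = [
                h
                for h in pssm.scan_sequence(target, r.cds, transcript_id=r.transcript_id)
                if h.score >= sel.t_star
            ]
            hits_by_id[r.transcript_id] = hits
            all_hits.extend(hits)
        report = pssm.occurrence_stats(hits_by_id, labels)
        pssm.write_hits_tsv(all_hits, outdir / "motif_hits.tsv")
        (outdir / "occurrence.json").write_text(
            json.dumps(
                {
                    "t_star": sel.t_star,
                    "t_star_p": sel.fisher_p,
                    "occurrence": report.to_dict(),
                },
                indent=2,
                default=float,
            )
            + "\n"
        )
        manifest["stages"]["motif-scan"] = {
            "t_star": sel.t_star,
            "n_hits": len(all_hits),
        }

    if "null-rank" in config.stages:
        if target is None:
            raise FileNotFoundError("null-rank stage requires motif-scan")
        ranking = nullmodels.rank_against_null(
            target,
            [r.cds for r in pos_recs],
            [r.cds for r in neg_recs],
            n_null=n_null,
            fpr_grid=config.fpr_grid,
            seed=_stage_seed(config.seed, "null-rank"),
        )
        (outdir / "null_ranking.json").write_text(
            json.dumps(ranking.to_dict(), indent=2) + "\n"
        )
        manifest["stages"]["null-rank"] = {
            "n_null": ranking.n_null,
            "min_percentile": ranking.min_percentile,
        }

    if "enrich" in config.stages:
        annotations, _ = simulate.gen_category_annotations(
            records,
            n_terms=config.n_terms,
            planted=[(25, 0.0)],
            seed=_stage_seed(config.seed, "enrich"),
        )
        rows = enrichment.term_enrichment(annotations, labels)
        rows = enrichment.resampling_adjust(
            rows,
            annotations,
            labels,
            n_resamples=config.n_resamples,
            seed=_stage_seed(config.seed, "enrich") + 1,
        )
        enrichment.write_enrichment_tsv(rows, outdir / "enrichment.tsv")
        classes = {r.leader_class for r in records}
        if len(classes) > 1:
            cmh, audit = enrichment.length_matched_association(
                records, n_strata=config.n_strata
            )
            (outdir / "length_matched.json").write_text(
                json.dumps({"cmh": cmh.to_dict(), "strata": audit}, indent=2) + "\n"
            )
        else:
            # length-matched association needs a leader-vs-other contrast
            (outdir / "length_matched.json").write_text(
                json.dumps({"cmh": None, "note": "single leader class"}, indent=2)
                + "\n"
            )
        manifest["stages"]["enrich"] = {
            "n_terms": len(rows),
            "top_term": rows[0].term_id if rows else None,
        }

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest
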