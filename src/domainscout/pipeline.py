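"""End-to-end orchestration: one config, one reproducible run directory.

Stages run in dependency order (conservation → delimitation → HMM search →
architecture census → sequence tree → structure tree); every artifact is
written in the dialects the individual modules define, the resolved config
is echoed into the run directory, and a machine-readable ``report.json``
aggregates the headline numbers.  The global seed fans out to per-stage
seeds by stable hashing of stage names, so toggling one stage never shifts
another's randomness.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import architecture as arch_mod
from . import conservation as cons
from . import hmm as hmm_mod
from . import seqphylo, structphylo, synthetic
from .msa import Msa, read_fasta_msa, read_fasta_sequences, write_fasta
from .trees import tree_to_newick, write_phylip

log = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Every stage toggle and parameter of the discovery workflow."""

    seed: int = 0
    outdir: str = "run"
    # stage toggles
    run_conservation: bool = True
    run_delimit: bool = True
    run_hmmsearch: bool = True
    run_census: bool = True
    run_seqtree: bool = True
    run_structtree: bool = True
    # optional real inputs (synthetic defaults are generated when absent)
    msa_path: str | None = None
    database_path: str | None = None
    hits_path: str | None = None
    reference_id: str | None = None
    # stage parameters (defaults are the workflow's standard settings)
    window: int = 10
    threshold: float = 4.0
    min_len: int = 25
    merge_gap: int = 10
    anchors: list[int] = field(default_factory=list)
    evalue_cutoff: float = 1e-10
    iterations: int = 3
    pseudocount_matrix: str = "BLOSUM90"
    n_decoys: int = 200
    census_target: str = "VASt"
    census_n: int = 500
    bootstrap_reps: int = 100
    distance_model: str = "kimura"
    fm_power: float = 2.0
    # synthetic study conditions
    family_n: int = 14
    domain_len: int = 193
    p_sub: float = 0.16
    db_family: int = 20
    db_background: int = 80
    struct_groups: int = 2
    struct_per_group: int = 5
    struct_sigma: float = 0.5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def stage_seed(self, stage: str) -> int:
        return (zlib.crc32(f"{stage}:{self.seed}".encode()) ^ self.seed) % (2 ** 31)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the aggregated report dict."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(dataclasses.asdict(config)))
    report: dict = {"schema_version": REPORT_SCHEMA_VERSION, "seed": config.seed}

    msa: Msa | None = None
    reference = config.reference_id
    fam = None
    if config.msa_path:
        msa = read_fasta_msa(config.msa_path)
        if reference is None:
            reference = msa.ids[0]
    elif config.run_conservation or config.run_delimit or config.run_hmmsearch:
        fam = synthetic.simulate_domain_family(
            synthetic.FamilyParams(
                n=config.family_n, domain_len=config.domain_len, p_sub=config.p_sub
            ),
            seed=config.stage_seed("family"),
        )
        msa = fam.true_alignment
        reference = msa.ids[0]
        write_fasta(msa.records, out / "family.afa")

    profile = None
    try:
        if config.run_conservation:
            profile = cons.smooth_profile(
                cons.conservation_profile(msa), window=config.window
            )
            cons.write_profile_tsv(profile, out / "profile.tsv")
            report["conservation"] = {
                "n_columns": len(profile),
                "mean_smoothed": sum(profile.smoothed) / len(profile),
            }
    except Exception as exc:  # noqa: BLE001
        raise StageError("conservation", exc) from exc

    segments = []
    try:
        if config.run_delimit:
            if profile is None:
                profile = cons.smooth_profile(
                    cons.conservation_profile(msa), window=config.window
                )
            segments = cons.delimit_domains(
                profile, msa, reference,
                threshold=config.threshold, min_len=config.min_len,
                merge_gap=config.merge_gap, anchors=config.anchors,
            )
            cons.write_segments_tsv(segments, out / "segments.tsv", reference)
            report["delimit"] = {
                "reference": reference,
                "segments": [
                    {
                        "start_col": s.start_col, "end_col": s.end_col,
                        "start_res": s.start_res, "end_res": s.end_res,
                        "length_res": s.length_res,
                    }
                    for s in segments
                ],
            }
            if len(msa) >= 2 and segments:
                seg = max(segments, key=lambda s: s.length_res)
                report["delimit"]["mean_pairwise_identity_domain"] = (
                    cons.mean_pairwise_identity(msa, (seg.start_col, seg.end_col))
                )
                report["delimit"]["min_identity_to_reference"] = (
                    cons.min_identity_to_reference(msa, reference)
                )
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("delimit", exc) from exc

    try:
        if config.run_hmmsearch:
            if config.database_path:
                database = read_fasta_sequences(config.database_path)
                truth = None
            else:
                database, truth, _ = synthetic.make_search_database(
                    n_family=config.db_family,
                    n_background=config.db_background,
                    params=synthetic.FamilyParams(
                        n=config.db_family, domain_len=config.domain_len,
                        p_sub=config.p_sub,
                    ),
                    seed=config.stage_seed("database"),
                    consensus=fam.consensus if fam is not None else None,
                )
                write_fasta(database, out / "database.fasta")
            if segments:
                seg = max(segments, key=lambda s: s.length_res)
                seed_msa = msa.select_columns(range(seg.start_col, seg.end_col + 1))
            else:
                seed_msa = msa
            final_hmm, per_iter = hmm_mod.iterative_search(
                seed_msa, database,
                evalue_cutoff=config.evalue_cutoff,
                max_iter=config.iterations,
                pseudocount_matrix=config.pseudocount_matrix,
                n_decoys=config.n_decoys,
                calibration_seed=config.stage_seed("calibration"),
            )
            hmm_mod.save_hmm(final_hmm, out / "model.hmm")
            logo = hmm_mod.relative_entropy_logo(final_hmm)
            hmm_mod.write_logo_tsv(logo, out / "logo.tsv")
            for it, hits in enumerate(per_iter, start=1):
                hmm_mod.write_hits_tsv(hits, out / f"hits_iter{it}.tsv")
            final_hits = per_iter[-1]
            report["hmmsearch"] = {
                "match_states": final_hmm.M,
                "hits_per_iteration": [len(h) for h in per_iter],
                "n_hits": len(final_hits),
            }
            if truth is not None:
                hit_ids = {h.target_id for h in final_hits}
                tp = len(hit_ids & set(truth))
                report["hmmsearch"]["recall"] = tp / len(truth)
                report["hmmsearch"]["precision"] = (
                    tp / len(hit_ids) if hit_ids else 1.0
                )
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("hmmsearch", exc) from exc

    try:
        if config.run_census:
            if config.hits_path:
                archs = arch_mod.read_hits_tsv(config.hits_path)
            else:
                archs = synthetic.simulate_architecture_set(
                    n=config.census_n, seed=config.stage_seed("census")
                )
                arch_mod.write_hits_tsv(archs, out / "annotations.tsv")
            summary = arch_mod.architecture_summary(archs, config.census_target)
            (out / "census.json").write_text(arch_mod.summary_to_json(summary))
            report["census"] = {
                "n_proteins": summary.n_proteins,
                "fraction_single_copy": summary.fraction_single_copy,
                "fraction_target_only": summary.fraction_target_only,
                "cooccurrence": summary.cooccurrence,
            }
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("census", exc) from exc

    try:
        if config.run_seqtree:
            if msa is None:
                raise ValueError("sequence tree stage needs an alignment")
            if fam is not None:
                start, end = synthetic.family_domain_columns(fam)
                tree_msa = msa.select_columns(range(start, end + 1))
            else:
                tree_msa, _ = seqphylo.trim_columns(msa, max_gap_fraction=0.2)
            tree_msa, clusters = seqphylo.remove_redundant(tree_msa, 0.98)
            dm = seqphylo.pairwise_distance(tree_msa, config.distance_model)
            write_phylip(dm, out / "seq_distances.phy")
            tree, used = seqphylo.bootstrap_support(
                tree_msa, config.distance_model,
                n_reps=config.bootstrap_reps, seed=config.stage_seed("bootstrap"),
            )
            (out / "seq_tree.nwk").write_text(tree_to_newick(tree) + "\n")
            report["seqtree"] = {
                "n_sequences": len(tree_msa),
                "bootstrap_replicates_used": used,
            }
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("seqtree", exc) from exc

    try:
        if config.run_structtree:
            structs, groups, smsa = synthetic.simulate_structures(
                n_per_group=config.struct_per_group,
                n_groups=config.struct_groups,
                sigma=config.struct_sigma,
                seed=config.stage_seed("structures"),
            )
            dm, pairs = structphylo.structural_distance_matrix(structs, smsa)
            write_phylip(dm, out / "struct_distances.phy")
            structphylo.write_superposition_report(pairs, out / "superpositions.tsv")
            fm = structphylo.fitch_margoliash_tree(dm, power=config.fm_power)
            (out / "struct_tree.nwk").write_text(tree_to_newick(fm.tree) + "\n")
            report["structtree"] = {
                "n_structures": len(structs),
                "fm_error": fm.error,
                "groups": sorted(set(groups)),
            }
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("structtree", exc) from exc

    (out / "report.json").write_text(json.dumps(report, indent=2) + "\n")
    return report
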