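"""End-to-end decoy scoring: consensus, clustering, interfaces, selection.

The decision logic mirrors a scorer's workflow in a blind docking
experiment.  After filtering and renumbering, the ensemble is ranked by
contact-conservation consensus and clustered on contact fingerprints.  A
candidate pool is drawn from the top of the global consensus ranking plus
the top models of each of the most populated clusters.  The sharpness of
the consensus — the Maxscore, the normalized score of the top-ranked
model — decides the selection regime:

* **strong consensus** (Maxscore >= 0.1): the ensemble agrees on an
  interface; all submitted models come from the global consensus ranking;
* **weak consensus** (Maxscore < 0.1): the consensus cannot be trusted;
  one model is taken from the top of the global ranking and the rest from
  distinct clusters in population order, diversifying the submission.

Candidates with excessive steric clashes (more than 25 inter-chain atom
pairs within 3 Å) are excluded.  The survivors are finally ordered by the
extent of their interface — contact count first, then buried interface
area, then consensus score — since among comparably consensual poses the
one with the more extended interface tends to be the more accurate.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .clustering import (
    ClusterSet,
    complete_linkage,
    default_t,
    distance_vector,
    flat_clusters_maxclust,
    per_cluster_rankings,
)
from .config import PipelineConfig
from .contacts import ContactMap, compute_contact_map
from .interface import InterfaceReport, interface_report
from .model_io import (
    FilterReport,
    Model,
    TargetSpec,
    filter_ensemble,
    read_ensemble,
    renumber_ensemble,
)
from .scoring import (
    ConservationMap,
    Ranking,
    conservation_rates,
    export_consensus_map,
    rank_models,
)

__all__ = [
    "Candidate",
    "SelectionResult",
    "PipelineResult",
    "build_candidate_pool",
    "choose_regime",
    "final_rank",
    "run_pipeline",
]


@dataclass
class Candidate:
    """A model in the selection pool, with its provenance."""

    model_id: str
    S_norm: float
    consrank_rank: int | None = None          # 1-based global consensus rank
    cluster_sources: list[tuple[int, int]] = field(default_factory=list)
    # (cluster number, 1-based within-cluster rank)
    report: InterfaceReport | None = None

    @property
    def sources(self) -> list[str]:
        out = []
        if self.consrank_rank is not None:
            out.append(f"consrank:{self.consrank_rank}")
        out.extend(f"cluster{c}:{r}" for c, r in self.cluster_sources)
        return out


@dataclass
class SelectionResult:
    """The final ranked selection and how it was arrived at."""

    selected: list[Candidate]
    maxscore: float
    regime: str                                # "strong-consensus" | "weak-consensus"
    exclusions: dict[str, str] = field(default_factory=dict)

    def to_tsv(self) -> str:
        lines = ["position\tmodel_id\tn_contacts\tinterface_area\tn_clashes\tS_norm\tsources"]
        for i, c in enumerate(self.selected, start=1):
            r = c.report
            lines.append(
                f"{i}\t{c.model_id}\t{r.n_contacts}\t{r.interface_area:.1f}"
                f"\t{r.n_clashes}\t{c.S_norm:.6f}\t{','.join(c.sources)}"
            )
        return "\n".join(lines) + "\n"


def build_candidate_pool(
    ranking: Ranking,
    cluster_rankings: Mapping[int, Ranking],
    config: PipelineConfig,
    reports: Mapping[str, InterfaceReport],
) -> list[Candidate]:
    """Union of top consensus models and top per-cluster models.

    A model reached through both routes appears once, with both
    provenances recorded.  ``reports`` supplies the interface report for
    every pooled model.
    """
    pool: dict[str, Candidate] = {}
    for entry in ranking.top(config.top_consrank_pool):
        pool[entry.model_id] = Candidate(
            model_id=entry.model_id,
            S_norm=entry.S_norm,
            consrank_rank=entry.rank,
        )
    for ci in sorted(cluster_rankings):
        if ci >= config.top_clusters:
            continue
        for entry in cluster_rankings[ci].top(config.per_cluster):
            cand = pool.get(entry.model_id)
            if cand is None:
                cand = pool[entry.model_id] = Candidate(
                    model_id=entry.model_id,
                    S_norm=ranking.entry(entry.model_id).S_norm,
                )
            cand.cluster_sources.append((ci, entry.rank))
    for cand in pool.values():
        cand.report = reports[cand.model_id]
    return list(pool.values())


def choose_regime(maxscore: float, config: PipelineConfig) -> str:
    """Selection regime from consensus sharpness."""
    if not 0.0 < maxscore <= 1.0:
        raise ValueError("maxscore must be in (0, 1]")
    return (
        "strong-consensus"
        if maxscore >= config.maxscore_threshold
        else "weak-consensus"
    )


def _interface_key(c: Candidate) -> tuple:
    r = c.report
    return (-r.n_contacts, -r.interface_area, -c.S_norm, c.model_id)


def final_rank(
    pool: Sequence[Candidate], regime: str, config: PipelineConfig
) -> SelectionResult:
    """Apply the clash filter, the regime quota, and the interface ordering."""
    if not pool:
        raise ValueError("empty candidate pool")
    exclusions: dict[str, str] = {}
    survivors = []
    for c in pool:
        if c.report is None:
            raise ValueError(f"{c.model_id}: candidate has no interface report")
        if c.report.n_clashes > config.clash_max:
            exclusions[c.model_id] = f"clashes:{c.report.n_clashes}"
        else:
            survivors.append(c)

    maxscore = max((c.S_norm for c in pool if c.consrank_rank == 1), default=None)
    if maxscore is None:
        maxscore = max(c.S_norm for c in pool)

    if regime == "strong-consensus":
        quota = [c for c in survivors if c.consrank_rank is not None]
        quota.sort(key=_interface_key)
        selected = quota[: config.n_submit]
    elif regime == "weak-consensus":
        consrank_sourced = sorted(
            (c for c in survivors if c.consrank_rank is not None),
            key=lambda c: c.consrank_rank,
        )
        if not consrank_sourced:
            raise ValueError("weak regime needs at least one consensus-ranked survivor")
        head = consrank_sourced[0]
        # one model per cluster in population order, then second picks
        per_cluster: dict[int, list[Candidate]] = {}
        for c in survivors:
            for ci, rank_in_cluster in c.cluster_sources:
                per_cluster.setdefault(ci, []).append(c)
        for ci in per_cluster:
            per_cluster[ci].sort(
                key=lambda c: min(r for cc, r in c.cluster_sources if cc == ci)
            )
        rest: list[Candidate] = []
        chosen = {head.model_id}
        for _round in range(config.per_cluster):
            for ci in sorted(per_cluster):
                if len(rest) >= config.n_submit - 1:
                    break
                for c in per_cluster[ci]:
                    if c.model_id not in chosen:
                        rest.append(c)
                        chosen.add(c.model_id)
                        break
        rest.sort(key=_interface_key)
        selected = [head] + rest
    else:
        raise ValueError(f"unknown regime {regime!r}")

    if len(selected) < config.n_submit:
        warnings.warn(
            f"only {len(selected)} clash-free candidates available "
            f"(requested {config.n_submit})"
        )
    return SelectionResult(
        selected=selected,
        maxscore=maxscore,
        regime=regime,
        exclusions=exclusions,
    )


@dataclass
class PipelineResult:
    """All artifacts of one pipeline run."""

    filter_report: FilterReport
    models: list[Model]
    maps: list[ContactMap]
    rates: ConservationMap
    ranking: Ranking
    clusterset: ClusterSet
    cluster_rankings: dict[int, Ranking]
    reports: dict[str, InterfaceReport]
    pool: list[Candidate]
    selection: SelectionResult


def _stage(name: str):
    """Tag exceptions with the pipeline stage they came from."""
    import contextlib

    @contextlib.contextmanager
    def cm():
        try:
            yield
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

    return cm()


def run_pipeline(
    inputs: Sequence[str | Path] | Sequence[Model],
    target: TargetSpec,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full scoring pipeline on an ensemble.

    ``inputs`` may be PDB file paths or already-parsed models.  The run is
    a pure function of (inputs, config): repeated runs produce identical
    results.  When ``out_dir`` is given every intermediate table is
    written there as tab-separated text plus a JSON run manifest.
    """
    config = config or PipelineConfig()
    symmetric = target.is_symmetric_pair()
    partition = target.partition()

    if inputs and isinstance(inputs[0], Model):
        models, failures = list(inputs), []
    else:
        with _stage("read"):
            models, failures = read_ensemble(inputs)

    def contact_count(model: Model) -> int:
        return compute_contact_map(
            model, cutoff=config.contact_cutoff, symmetric=symmetric
        ).M

    with _stage("filter"):
        kept, report = filter_ensemble(
            models,
            target,
            contact_count,
            identity_min=config.seq_identity_min,
            coverage_min=config.coverage_min,
            read_failures=failures,
        )
    with _stage("renumber"):
        renumbered = renumber_ensemble(
            kept, target, config.seq_identity_min, config.coverage_min
        )
    with _stage("contacts"):
        maps = [
            compute_contact_map(
                m, cutoff=config.contact_cutoff, chain_pair=partition,
                symmetric=symmetric,
            )
            for m in renumbered
        ]
    with _stage("consensus"):
        rates = conservation_rates(maps)
        ranking = rank_models(maps, rates)
    with _stage("clustering"):
        dv = distance_vector(maps)
        Z = complete_linkage(dv)
        clusterset = flat_clusters_maxclust(
            Z, default_t(len(maps)), [m.model_id for m in maps]
        )
        cluster_rankings = per_cluster_rankings(clusterset, maps, config.top_clusters)
    with _stage("interfaces"):
        by_id = {m.model_id: m for m in renumbered}
        pool_ids = {e.model_id for e in ranking.top(config.top_consrank_pool)}
        for ci, cr in cluster_rankings.items():
            if ci < config.top_clusters:
                pool_ids.update(e.model_id for e in cr.top(config.per_cluster))
        reports = {
            mid: interface_report(
                by_id[mid], config, partition=partition, symmetric=symmetric
            )
            for mid in sorted(pool_ids)
        }
    with _stage("selection"):
        pool = build_candidate_pool(ranking, cluster_rankings, config, reports)
        regime = choose_regime(ranking.maxscore, config)
        selection = final_rank(pool, regime, config)

    result = PipelineResult(
        filter_report=report,
        models=renumbered,
        maps=maps,
        rates=rates,
        ranking=ranking,
        clusterset=clusterset,
        cluster_rankings=cluster_rankings,
        reports=reports,
        pool=pool,
        selection=selection,
    )
    if out_dir is not None:
        with _stage("write"):
            _write_artifacts(result, target, config, Path(out_dir))
    return result


def _write_artifacts(
    result: PipelineResult,
    target: TargetSpec,
    config: PipelineConfig,
    out: Path,
) -> None:
    import consrank

    out.mkdir(parents=True, exist_ok=True)
    (out / "filter_report.tsv").write_text(result.filter_report.to_tsv())
    (out / "filter_report.json").write_text(result.filter_report.to_json())
    (out / "ranking.tsv").write_text(result.ranking.to_tsv())
    (out / "clusters.tsv").write_text(result.clusterset.to_tsv())
    shape = tuple(len(s) for s in list(target.sequences.values())[:2])
    matrix, table = export_consensus_map(result.rates, shape=shape)
    np.savetxt(out / "consensus_matrix.tsv", matrix, fmt="%.6f", delimiter="\t")
    table.to_csv(out / "consensus_contacts.tsv", sep="\t", index=False)
    for ci, cr in result.cluster_rankings.items():
        (out / f"cluster_{ci}_ranking.tsv").write_text(cr.to_tsv())
    iface_lines = ["model_id\tn_contacts\tinterface_area\tn_clashes"]
    for mid, r in sorted(result.reports.items()):
        iface_lines.append(
            f"{mid}\t{r.n_contacts}\t{r.interface_area:.1f}\t{r.n_clashes}"
        )
    (out / "interface.tsv").write_text("\n".join(iface_lines) + "\n")
    (out / "selection.tsv").write_text(result.selection.to_tsv())
    manifest = {
        "package": "consrank",
        "version": getattr(consrank, "__version__", "unknown"),
        "config": config.to_dict(),
        "target_chains": {c: len(s) for c, s in target.sequences.items()},
        "maxscore": result.ranking.maxscore,
        "regime": result.selection.regime,
        "n_models_ranked": len(result.maps),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
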