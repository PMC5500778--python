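"""End-to-end pipeline: preprocess → NER → pairs → fit/assign → evaluate.

Each stage writes its artifact into the output directory so every step is
independently inspectable and a later stage can be re-run from saved
intermediates.  A run manifest (package version, seed, config hash) makes
runs reproducible: same config + seed → identical artifacts and report.

Cluster indices are canonical (sorted by ascending component σ).  The two
stock strategies are named after what they keep:

* ``"1"`` — filter the middle-spread and wide clusters (canonical indices
  1 and 2), keeping only the tight cluster around the drug name;
* ``"2"`` — filter only the wide cluster (canonical index 2), keeping the
  tight and middle clusters so nearly all true ADRs survive.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Union

from . import io as adrio
from .evaluate import (
    ContingencyTable,
    FilterReport,
    adr_coverage,
    apply_strategy,
    contingency,
    load_gold_csv,
)
from .lexicon import build_index, load_disorder_lexicon, load_drug_list
from .mixture import em_fit, map_assign
from .ner import recognize
from .pairing import enumerate_pairs
from .preprocess import preprocess_message

__all__ = ["PipelineConfig", "run_pipeline", "STRATEGIES"]

logger = logging.getLogger(__name__)

#: strategy name -> set of canonical cluster indices to filter out (K=3)
STRATEGIES = {"1": (1, 2), "2": (2,)}


@dataclass(frozen=True)
class PipelineConfig:
    corpus: Union[str, Path]
    disorder_lexicon: Union[str, Path]
    drug_list: Union[str, Path]
    gold: Optional[Union[str, Path]] = None
    out_dir: Union[str, Path] = "out"
    K: int = 3
    tol: float = 1e-8
    max_iter: int = 500
    seed: int = 0
    strategy: str = "1"

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: str(v) for k, v in asdict(self).items()}, sort_keys=True
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> FilterReport:
    """Run every stage, writing intermediates and a report to out_dir.

    With no gold annotations the evaluation stage is skipped and a report
    with NaN precision/recall is returned.  A corpus yielding zero pairs
    completes with a warning and a NaN-precision report rather than
    failing.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.K < 1:
        raise ValueError("K must be >= 1")

    stage = {"name": "init"}

    def _stage(name: str):
        stage["name"] = name
        logger.info("stage %s", name)

    try:
        _stage("preprocess")
        messages = adrio.read_corpus_jsonl(config.corpus)
        token_seqs = [preprocess_message(m) for m in messages]
        adrio.write_tokens_jsonl(out / "tokens.jsonl", token_seqs)

        _stage("ner")
        disorders = load_disorder_lexicon(config.disorder_lexicon)
        drugs = load_drug_list(config.drug_list)
        disorder_index = build_index(disorders, "exact-stemmed")
        drug_index = build_index(drugs, "fuzzy")
        mentions_by_msg = {
            ts.message_id: recognize(ts, drug_index, disorder_index) for ts in token_seqs
        }
        adrio.write_mentions_jsonl(
            out / "mentions.jsonl", [m for ms in mentions_by_msg.values() for m in ms]
        )

        _stage("pairs")
        pairs = []
        for ts in token_seqs:
            pairs.extend(enumerate_pairs(mentions_by_msg[ts.message_id], len(ts)))
        adrio.write_pairs_tsv(out / "pairs.tsv", pairs)

        _stage("fit")
        distances = [p.distance for p in pairs]
        if len(distances) < 2 * config.K:
            logger.warning(
                "only %d pairs: skipping mixture fit, report will be NaN", len(distances)
            )
            model = None
            clusters: list[int] = [0] * len(pairs)
        else:
            fit = em_fit(
                distances, K=config.K, seed=config.seed,
                tol=config.tol, max_iter=config.max_iter,
            )
            model = fit.model
            adrio.write_model_json(
                out / "model.json", model,
                loglik=fit.loglik_trace[-1], n_iter=fit.n_iter, converged=fit.converged,
            )
            clusters = [int(c) for c in map_assign(model, distances)]
        adrio.write_pairs_tsv(out / "assigned.tsv", pairs, clusters=clusters)

        _stage("evaluate")
        filter_set = STRATEGIES.get(config.strategy)
        if filter_set is None:
            raise ValueError(f"unknown strategy {config.strategy!r}; pick one of {sorted(STRATEGIES)}")
        filter_set = tuple(k for k in filter_set if k < config.K) or (config.K - 1,)
        if config.gold is not None and model is not None:
            gold = load_gold_csv(config.gold)
            table = contingency(list(zip(pairs, clusters)), gold, n_clusters=config.K)
            report = apply_strategy(table, filter_set, name=f"strategy-{config.strategy}")
            extra = {
                "adr_coverage_kept": adr_coverage(
                    table, set(range(config.K)) - set(filter_set)
                ),
                "table_other": list(table.other),
                "table_adr": list(table.adr),
            }
        else:
            if config.gold is None:
                logger.warning("no gold annotations: report carries NaN metrics")
            report = FilterReport(
                strategy=f"strategy-{config.strategy}",
                filtered_clusters=tuple(filter_set),
                filtered_other=0, filtered_adr=0, kept_other=0, kept_adr=0,
                precision=math.nan, recall=math.nan, reduction=math.nan,
            )
            extra = {}
        adrio.write_report_json(out / "report.json", report, extra=extra)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage['name']}: {exc}") from exc

    manifest = {
        "package": "adrfilter",
        "version": __import__("adrfilter").__version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_messages": len(messages),
        "n_pairs": len(pairs),
        "strategy": config.strategy,
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
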