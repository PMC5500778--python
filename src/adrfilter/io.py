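"""File-format contracts: JSONL corpus/tokens/mentions, TSV pairs, JSON models.

All readers tolerate a UTF-8 BOM; writers never emit one.  Malformed input
raises :class:`FormatError` naming the file, line number and field.  Writers
canonicalise (sorted JSON keys, ``\\n`` line endings) so write∘read is the
identity on canonical files.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .evaluate import FilterReport, GoldLabel
from .mixture import MixtureModel
from .ner import Mention
from .pairing import Pair
from .preprocess import Message, TokenSequence

__all__ = [
    "FormatError",
    "read_corpus_jsonl", "write_corpus_jsonl",
    "read_tokens_jsonl", "write_tokens_jsonl",
    "read_mentions_jsonl", "write_mentions_jsonl",
    "write_pairs_tsv", "read_pairs_tsv",
    "write_gold_csv",
    "write_model_json", "read_model_json",
    "write_report_json",
]

PathLike = Union[str, Path]

PAIR_COLUMNS = [
    "message_id", "drug_name", "llt_id", "llt_label", "pt_id", "pt_label",
    "disorder_pos", "relative_position", "distance", "message_length",
]


class FormatError(ValueError):
    """Malformed input file; message names file, line and field."""


def _iter_jsonl(path: PathLike):
    with open(path, encoding="utf-8-sig") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                yield lineno, json.loads(line)
            except json.JSONDecodeError as exc:
                raise FormatError(f"{path}:{lineno}: invalid JSON ({exc})") from exc


def _require(obj: dict, fields: Sequence[str], path: PathLike, lineno: int) -> None:
    for f in fields:
        if f not in obj:
            raise FormatError(f"{path}:{lineno}: missing field {f!r}")


def _write_jsonl(path: PathLike, records: Iterable[dict]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for rec in records:
            fh.write(json.dumps(rec, ensure_ascii=False, sort_keys=True))
            fh.write("\n")


def read_corpus_jsonl(path: PathLike) -> list[Message]:
    out = []
    for lineno, obj in _iter_jsonl(path):
        _require(obj, ("message_id", "text"), path, lineno)
        out.append(
            Message(
                message_id=str(obj["message_id"]),
                text=obj["text"],
                source=obj.get("source", ""),
                date=obj.get("date"),
            )
        )
    return out


def write_corpus_jsonl(path: PathLike, messages: Iterable[Message]) -> None:
    _write_jsonl(
        path,
        (
            {"message_id": m.message_id, "text": m.text, "source": m.source, "date": m.date}
            for m in messages
        ),
    )


def read_tokens_jsonl(path: PathLike) -> list[TokenSequence]:
    out = []
    for lineno, obj in _iter_jsonl(path):
        _require(obj, ("message_id", "tokens"), path, lineno)
        out.append(TokenSequence(tokens=tuple(obj["tokens"]), message_id=str(obj["message_id"])))
    return out


def write_tokens_jsonl(path: PathLike, sequences: Iterable[TokenSequence]) -> None:
    _write_jsonl(
        path,
        ({"message_id": s.message_id, "tokens": list(s.tokens)} for s in sequences),
    )


_MENTION_FIELDS = ("message_id", "kind", "surface", "canonical_id", "start_pos", "span_len")


def read_mentions_jsonl(path: PathLike) -> list[Mention]:
    out = []
    for lineno, obj in _iter_jsonl(path):
        _require(obj, _MENTION_FIELDS, path, lineno)
        out.append(
            Mention(
                message_id=str(obj["message_id"]),
                kind=obj["kind"],
                surface=obj["surface"],
                canonical_id=str(obj["canonical_id"]),
                start_pos=int(obj["start_pos"]),
                span_len=int(obj["span_len"]),
                pt_id=obj.get("pt_id"),
                pt_label=obj.get("pt_label", ""),
                canonical_label=obj.get("canonical_label", ""),
            )
        )
    return out


def write_mentions_jsonl(path: PathLike, mentions: Iterable[Mention]) -> None:
    _write_jsonl(
        path,
        (
            {
                "message_id": m.message_id,
                "kind": m.kind,
                "surface": m.surface,
                "canonical_id": m.canonical_id,
                "start_pos": m.start_pos,
                "span_len": m.span_len,
                "pt_id": m.pt_id,
                "pt_label": m.pt_label,
                "canonical_label": m.canonical_label,
            }
            for m in mentions
        ),
    )


def write_pairs_tsv(
    path: PathLike, pairs: Iterable[Pair], clusters: Optional[Sequence[int]] = None
) -> None:
    """Write the pair table; with ``clusters`` adds an assignment column."""
    pairs = list(pairs)
    columns = PAIR_COLUMNS + (["cluster"] if clusters is not None else [])
    if clusters is not None and len(clusters) != len(pairs):
        raise ValueError("clusters must align with pairs")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(columns)
        for i, p in enumerate(pairs):
            row = [
                p.message_id,
                p.drug_name,
                p.llt_id,
                p.disorder_mention.canonical_label,
                p.pt_id,
                p.disorder_mention.pt_label,
                p.disorder_mention.start_pos,
                p.relative_position,
                p.distance,
                p.message_length,
            ]
            if clusters is not None:
                row.append(clusters[i])
            writer.writerow(row)


def read_pairs_tsv(path: PathLike) -> list[dict]:
    """Read a pair table back as dicts (distance and positions as ints)."""
    out = []
    with open(path, encoding="utf-8-sig", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = [c for c in PAIR_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                row["disorder_pos"] = int(row["disorder_pos"])
                row["distance"] = int(row["distance"])
                row["message_length"] = int(row["message_length"])
                if "cluster" in row and row["cluster"] not in (None, ""):
                    row["cluster"] = int(row["cluster"])
            except (TypeError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: non-integer numeric field ({exc})") from exc
            out.append(row)
    return out


def write_gold_csv(path: PathLike, gold: Iterable[GoldLabel]) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["message_id", "llt_id", "start_pos", "label"])
        for g in gold:
            writer.writerow([g.message_id, g.llt_id, g.start_pos, g.label])


def write_model_json(
    path: PathLike,
    model: MixtureModel,
    loglik: Optional[float] = None,
    n_iter: Optional[int] = None,
    converged: Optional[bool] = None,
) -> None:
    payload = model.to_dict()
    payload.update({"loglik": loglik, "n_iter": n_iter, "converged": converged})
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_model_json(path: PathLike) -> MixtureModel:
    with open(path, encoding="utf-8-sig") as fh:
        payload = json.load(fh)
    for f in ("weights", "means", "sds"):
        if f not in payload:
            raise FormatError(f"{path}: missing field {f!r}")
    return MixtureModel.from_dict(payload)


def write_report_json(path: PathLike, report: FilterReport, extra: Optional[dict] = None) -> None:
    payload = report.to_dict()
    if extra:
        payload.update(extra)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
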