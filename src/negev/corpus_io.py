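"""Directory-level corpus I/O.

A corpus directory holds one standoff triple per document
(``<doc>.txt`` / ``<doc>.a1`` / ``<doc>.a2``), a ``parses.json`` file with
the fixture parse records keyed by sentence text, and — for generated
corpora — a ``gold.tsv`` table of planted polarities.
"""

from __future__ import annotations

import csv
import json
import os
from typing import Optional

from .parse_layer import FixtureBackend
from .standoff_io import Document, read_standoff, write_standoff
from .synthetic_corpus import GoldRecord


def save_corpus(
    directory: str,
    docs: list[Document],
    backend: Optional[FixtureBackend] = None,
    gold: Optional[list[GoldRecord]] = None,
) -> None:
    os.makedirs(directory, exist_ok=True)
    for doc in docs:
        a1, a2 = write_standoff(doc)
        base = os.path.join(directory, doc.doc_id)
        with open(base + ".txt", "w") as fh:
            fh.write(doc.text + "\n")
        with open(base + ".a1", "w") as fh:
            fh.write(a1)
        with open(base + ".a2", "w") as fh:
            fh.write(a2)
    if backend is not None:
        with open(os.path.join(directory, "parses.json"), "w") as fh:
            fh.write(backend.to_json())
    if gold is not None:
        with open(os.path.join(directory, "gold.tsv"), "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["doc_id", "event_id", "polarity", "negation_type",
                        "template_id", "is_complex", "sentence_index"])
            for r in gold:
                w.writerow([r.doc_id, r.event_id, r.polarity,
                            r.negation_type or "", r.template_id,
                            int(r.is_complex), r.sentence_index])


def load_corpus(directory: str) -> tuple[list[Document], Optional[FixtureBackend]]:
    docs = []
    for name in sorted(os.listdir(directory)):
        if not name.endswith(".txt") or name == "gold.tsv":
            continue
        base = os.path.join(directory, name[:-4])
        with open(base + ".txt") as fh:
            text = fh.read().rstrip("\n")
        a1 = a2 = ""
        if os.path.exists(base + ".a1"):
            with open(base + ".a1") as fh:
                a1 = fh.read()
        if os.path.exists(base + ".a2"):
            with open(base + ".a2") as fh:
                a2 = fh.read()
        doc = read_standoff(text, a1, a2)
        doc.doc_id = name[:-4]
        docs.append(doc)
    backend = None
    parses = os.path.join(directory, "parses.json")
    if os.path.exists(parses):
        with open(parses) as fh:
            backend = FixtureBackend.from_json(fh.read())
    return docs, backend


def load_gold(directory: str) -> list[GoldRecord]:
    path = os.path.join(directory, "gold.tsv")
    records: list[GoldRecord] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            records.append(GoldRecord(
                row["doc_id"], row["event_id"], row["polarity"],
                row["negation_type"] or None, row["template_id"],
                bool(int(row["is_complex"])), int(row["sentence_index"]),
            ))
    return records
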