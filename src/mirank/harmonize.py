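"""miRNA name harmonization across prediction sources.

Different resources name mature miRNAs inconsistently (case differences,
and distinct precursor-derived names for one mature sequence, e.g.
``hsa-mir-125b-1-3p`` and ``hsa-mir-125b-2-3p``).  miRNAs with the same
mature sequence are treated as identical: all names sharing a sequence
collapse onto one canonical key, chosen as the lexicographically smallest
case-folded alias so the result is independent of input order.  Without a
sequence table harmonization degrades to case-folding only.
"""

from __future__ import annotations

import logging

import pandas as pd

from .ingest import deduplicate_records

logger = logging.getLogger("mirank")


class HarmonizeError(ValueError):
    """Fatal harmonization problem: sequence conflict or unmapped name."""


def read_sequence_table(path) -> dict[str, str]:
    """Read a name→sequence map from two-column TSV or FASTA.

    FASTA is detected by a leading ``>``; the first whitespace-delimited
    header token is the name.  Sequences are upper-cased with T→U so DNA-
    and RNA-alphabet sources compare equal.
    """
    with open(path) as fh:
        first = fh.read(1)
    sequences: dict[str, str] = {}
    if first == ">":
        name = None
        chunks: list[str] = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith(">"):
                    if name is not None:
                        sequences[name] = "".join(chunks)
                    name = line[1:].split()[0]
                    chunks = []
                elif line:
                    chunks.append(line)
            if name is not None:
                sequences[name] = "".join(chunks)
    else:
        frame = pd.read_csv(path, sep="\t", header=None, comment="#",
                            names=["name", "sequence"], dtype=str)
        sequences = dict(zip(frame["name"], frame["sequence"]))
    return {str(k).strip(): str(v).strip().upper().replace("T", "U")
            for k, v in sequences.items()}


def build_identity_map(names, sequences: dict[str, str] | None = None
                       ) -> dict[str, str]:
    """Map every input name to its canonical key.

    Names whose sequences are equal share one key; names without sequence
    data map to their own case-folded form.  The canonical key is the
    smallest case-folded alias among *all* names the sequence table lists
    for that sequence — not only the aliases observed in ``names`` — so a
    dataset in which one alias never surfaces still canonicalizes to the
    same key.  One name appearing with two different sequences is a fatal
    inconsistency in the sequence source.
    """
    names = list(names)
    if not names:
        raise HarmonizeError("no miRNA names supplied")
    sequences = sequences or {}
    folded_seq: dict[str, str] = {}
    for name, seq in sequences.items():
        key = name.casefold()
        if key in folded_seq and folded_seq[key] != seq:
            raise HarmonizeError(
                f"name {name!r} has conflicting sequences "
                f"{folded_seq[key]!r} and {seq!r}"
            )
        folded_seq[key] = seq

    # canonical alias per sequence, over the full alias set of the table
    canonical_for_seq: dict[str, str] = {}
    for folded, seq in folded_seq.items():
        if seq not in canonical_for_seq or folded < canonical_for_seq[seq]:
            canonical_for_seq[seq] = folded

    mapping: dict[str, str] = {}
    for name in names:
        folded = name.casefold()
        seq = folded_seq.get(folded)
        mapping[name] = folded if seq is None else canonical_for_seq[seq]
    logger.info("identity map: %d names -> %d identities",
                len(mapping), len(set(mapping.values())))
    return mapping


def apply_identity_map(records: pd.DataFrame, mapping: dict[str, str]
                       ) -> pd.DataFrame:
    """Replace miRNA keys by canonical keys and re-deduplicate.

    Aliases merged onto one key can create duplicate (miRNA, gene,
    database) triples; these collapse by maximum evaluation, so the record
    count never increases.
    """
    unmapped = set(records["mirna_key"]) - set(mapping)
    if unmapped:
        raise HarmonizeError(f"names missing from identity map: {sorted(unmapped)}")
    out = records.copy()
    out["mirna_key"] = out["mirna_key"].map(mapping)
    merged = deduplicate_records(out)
    logger.info("harmonize: %d records -> %d after alias merge",
                len(records), len(merged))
    return merged
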