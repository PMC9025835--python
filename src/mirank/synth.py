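"""Synthetic inputs with known ground truth for every pipeline stage.

Three input kinds are emulated: five-database prediction exports, a
tissue×miRNA normalized expression table, and a subject-level qPCR Cq
table.  A :class:`SimulationManifest` fixes every distribution parameter
and the seed, so a given (seed, manifest) pair reproduces byte-identical
files.

Prediction exports: each miRNA–gene pair is listed by a database with a
Bernoulli probability; numeric databases attach a native score drawn from
a Beta distribution rescaled to the dialect's native range.  A configured
set of *planted regulators* is listed with elevated probability and a
right-shifted score distribution, giving the scoring stage a recoverable
signal.  Alias groups plant nomenclature synonyms: one underlying miRNA
surfaces under several names (one chosen per export row), with a shared
mature sequence emitted in the sequence table.

Expression values are log-normal per brain region, with a configured
fraction of miRNAs missing entirely (the partial-data case).  Cq tables
follow a standard additive cycle-scale noise model: the case group's
target Cq is shifted by −log2(fold change), the reference assay is
unshifted and nearly noise-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .harmonize import apply_identity_map, build_identity_map
from .ingest import (RECORD_COLUMNS, RawDatabaseEntry, default_dialects,
                     deduplicate_records, standardize_records)

_NUCLEOTIDES = np.array(list("ACGU"))

# per-stage rng streams so regenerating one output never perturbs another
_STREAM_EXPORTS, _STREAM_EXPRESSION, _STREAM_CQ, _STREAM_SEQ = range(4)


@dataclass(frozen=True)
class SimulationManifest:
    """Every knob of the synthetic universe, with the seed."""

    seed: int = 0
    n_mirnas: int = 50
    target_genes: tuple[str, ...] = ("BDNF", "HTR1A", "SLC6A4",
                                     "NR3C1", "ZNF714", "NRIP3")
    n_planted: int = 5
    #: planted synonym sets; each group is the surface names of ONE miRNA
    alias_groups: tuple[tuple[str, ...], ...] = ()
    background_prediction_prob: float = 0.15
    planted_prediction_prob: float = 0.9
    #: Beta shape parameters for native scores, rescaled to each dialect
    background_beta: tuple[float, float] = (2.0, 2.0)
    planted_beta: tuple[float, float] = (8.0, 2.0)
    expression_regions: tuple[str, ...] = ("brain_1",
                                           "brain_cerebral_coretex_2")
    expression_meanlog: float = 0.8
    expression_sdlog: float = 0.6
    expression_missing_fraction: float = 0.2
    n_per_group: int = 20
    target_cq_mean: float = 28.0
    cq_noise_sd: float = 1.0
    reference_cq_mean: float = 20.0
    reference_cq_sd: float = 0.1
    #: assay id -> case/control fold change (>0) planted on the cycle scale
    fold_changes: dict = field(default_factory=lambda: {"assay_1": 1.0})

    def __post_init__(self):
        if any(f <= 0 for f in self.fold_changes.values()):
            raise ValueError("planted fold changes must be positive")
        if self.n_per_group < 2:
            raise ValueError("need at least 2 subjects per group")

    # -- naming ---------------------------------------------------------
    def underlying_names(self) -> list[str]:
        """Default name of each underlying miRNA (one per identity)."""
        return [f"hsa-miR-s{i:04d}-5p" for i in range(self.n_mirnas)]

    def surface_names(self, index: int) -> tuple[str, ...]:
        """Names under which underlying miRNA ``index`` appears in exports.

        Alias groups are attached to the LAST ``len(alias_groups)``
        underlying miRNAs so they never overlap the planted regulators
        (which are the first ``n_planted``).
        """
        n_grouped = len(self.alias_groups)
        first_grouped = self.n_mirnas - n_grouped
        if index >= first_grouped:
            return tuple(self.alias_groups[index - first_grouped])
        return (self.underlying_names()[index],)

    def canonical_name(self, index: int) -> str:
        return min(n.casefold() for n in self.surface_names(index))

    def planted_canonical(self) -> list[str]:
        return [self.canonical_name(i) for i in range(self.n_planted)]


def load_manifest(path) -> SimulationManifest:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for key in ("target_genes", "expression_regions", "background_beta",
                "planted_beta"):
        if key in raw:
            raw[key] = tuple(raw[key])
    if "alias_groups" in raw:
        raw["alias_groups"] = tuple(tuple(g) for g in raw["alias_groups"])
    return SimulationManifest(**raw)


def full_scale_manifest(seed: int = 0) -> SimulationManifest:
    """Preset echoing the in silico screen's size: 2511 candidate miRNAs."""
    return SimulationManifest(seed=seed, n_mirnas=2511, n_planted=10)


def _rng(manifest: SimulationManifest, stream: int) -> np.random.Generator:
    return np.random.default_rng([manifest.seed, stream])


# ---------------------------------------------------------------------------
# database exports

def generate_database_exports(manifest: SimulationManifest
                              ) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Five dialect-conformant export frames plus the truth table.

    The truth table lists every emitted (surface name, underlying canonical
    key, gene, database, raw value) so ingest and harmonization can be
    verified row for row.
    """
    rng = _rng(manifest, _STREAM_EXPORTS)
    dialects = default_dialects()
    exports = {name: [] for name in dialects}
    truth_rows = []
    for idx in range(manifest.n_mirnas):
        planted = idx < manifest.n_planted
        prob = (manifest.planted_prediction_prob if planted
                else manifest.background_prediction_prob)
        a, b = manifest.planted_beta if planted else manifest.background_beta
        names = manifest.surface_names(idx)
        for gene in manifest.target_genes:
            for db_name, dialect in dialects.items():
                if rng.random() >= prob:
                    continue
                surface = names[rng.integers(len(names))]
                if dialect.value_mode == "binary":
                    raw: str | float = "predicted"
                else:
                    lo, hi = dialect.native_range
                    raw = round(lo + (hi - lo) * rng.beta(a, b), 4)
                exports[db_name].append(
                    {"mirna": surface, "gene": gene, "score": raw})
                truth_rows.append({
                    "mirna_name": surface,
                    "canonical_key": manifest.canonical_name(idx),
                    "gene_symbol": gene,
                    "database_name": db_name,
                    "raw_value": raw,
                    "planted": planted,
                })
    frames = {name: pd.DataFrame(rows, columns=["mirna", "gene", "score"])
              for name, rows in exports.items()}
    truth = pd.DataFrame(truth_rows, columns=[
        "mirna_name", "canonical_key", "gene_symbol", "database_name",
        "raw_value", "planted"])
    return frames, truth


def generate_sequence_table(manifest: SimulationManifest) -> pd.DataFrame:
    """Name→sequence rows: all surface names of one miRNA share a 22-mer."""
    rng = _rng(manifest, _STREAM_SEQ)
    rows = []
    for idx in range(manifest.n_mirnas):
        seq = "".join(rng.choice(_NUCLEOTIDES, size=22))
        for name in manifest.surface_names(idx):
            rows.append({"name": name, "sequence": seq})
    return pd.DataFrame(rows, columns=["name", "sequence"])


# ---------------------------------------------------------------------------
# expression table

def generate_expression_table(manifest: SimulationManifest) -> pd.DataFrame:
    """Per-miRNA normalized expression per region (log-normal, some missing).

    Keys are canonical miRNA names so the table joins directly onto
    harmonized records.  A configured fraction of miRNAs is dropped
    entirely, emulating candidates with only partial data.
    """
    rng = _rng(manifest, _STREAM_EXPRESSION)
    keys = [manifest.canonical_name(i) for i in range(manifest.n_mirnas)]
    values = {
        region: rng.lognormal(manifest.expression_meanlog,
                              manifest.expression_sdlog, manifest.n_mirnas)
        for region in manifest.expression_regions
    }
    table = pd.DataFrame({"mirna_key": keys, **values})
    present = rng.random(manifest.n_mirnas) >= manifest.expression_missing_fraction
    return table[present].reset_index(drop=True)


# ---------------------------------------------------------------------------
# qPCR Cq table

def generate_cq_table(manifest: SimulationManifest
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Subject-level Cq table plus the truth table of planted fold changes.

    Case subjects' target Cq is shifted by −log2(fold) cycles (a 2-fold
    up-regulation costs one cycle); subject-level noise (sd
    ``cq_noise_sd``) rides on the target assay, and the reference assay
    carries only small technical noise.
    """
    rng = _rng(manifest, _STREAM_CQ)
    subjects = ([(f"case_{i:02d}", "case") for i in range(manifest.n_per_group)]
                + [(f"ctrl_{i:02d}", "control")
                   for i in range(manifest.n_per_group)])
    rows = []
    for assay, fold in sorted(manifest.fold_changes.items()):
        shift = -np.log2(fold)
        for subject_id, group in subjects:
            target = (manifest.target_cq_mean
                      + (shift if group == "case" else 0.0)
                      + rng.normal(0.0, manifest.cq_noise_sd))
            reference = (manifest.reference_cq_mean
                         + rng.normal(0.0, manifest.reference_cq_sd))
            rows.append({"subject_id": subject_id, "group": group,
                         "assay_id": assay,
                         "cq_target": round(target, 4),
                         "cq_reference": round(reference, 4)})
    cq = pd.DataFrame(rows, columns=["subject_id", "group", "assay_id",
                                     "cq_target", "cq_reference"])
    truth = pd.DataFrame(
        [{"assay_id": a, "fold_change": f}
         for a, f in sorted(manifest.fold_changes.items())])
    return cq, truth


# ---------------------------------------------------------------------------
# in-memory pipeline hookup and file output

def standardized_records(manifest: SimulationManifest) -> pd.DataFrame:
    """Generate exports and push them through standardize → harmonize.

    Convenience path used by tests and end-to-end runs that do not need
    the intermediate files on disk.
    """
    frames, _ = generate_database_exports(manifest)
    dialects = default_dialects()
    parts = []
    for db_name, frame in frames.items():
        entries = [RawDatabaseEntry(r.mirna, r.gene, r.score, db_name)
                   for r in frame.itertuples(index=False)]
        parts.append(standardize_records(entries, dialects[db_name]))
    records = deduplicate_records(
        pd.concat(parts, ignore_index=True) if parts
        else pd.DataFrame(columns=RECORD_COLUMNS))
    if records.empty:
        return records
    sequences = generate_sequence_table(manifest)
    seq_map = dict(zip(sequences["name"], sequences["sequence"]))
    mapping = build_identity_map(records["mirna_key"].unique(), seq_map)
    return apply_identity_map(records, mapping)


def write_all(manifest: SimulationManifest, outdir) -> dict[str, Path]:
    """Write every synthetic input (and truth tables) under ``outdir``."""
    outdir = Path(outdir)
    (outdir / "truth").mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    frames, export_truth = generate_database_exports(manifest)
    for db_name, frame in frames.items():
        paths[db_name] = outdir / f"{db_name}.tsv"
        frame.to_csv(paths[db_name], sep="\t", index=False)
    paths["sequences"] = outdir / "sequences.tsv"
    generate_sequence_table(manifest).to_csv(
        paths["sequences"], sep="\t", index=False, header=False)
    paths["expression"] = outdir / "expression.tsv"
    generate_expression_table(manifest).to_csv(
        paths["expression"], sep="\t", index=False)
    cq, cq_truth = generate_cq_table(manifest)
    paths["cq"] = outdir / "cq.tsv"
    cq.to_csv(paths["cq"], sep="\t", index=False)
    export_truth.to_csv(outdir / "truth" / "exports.tsv", sep="\t", index=False)
    cq_truth.to_csv(outdir / "truth" / "fold_changes.tsv", sep="\t", index=False)
    manifest_dict = asdict(manifest)
    manifest_dict["alias_groups"] = [list(g) for g in manifest.alias_groups]
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest_dict, fh, default_flow_style=None)
    return paths
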