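"""End-to-end orchestration of the sequence and structure analysis arms.

``run_peptidome_analysis`` takes per-allotype eluted-peptide lists and
emits the full set of motif reports: per-allotype position frequency
matrices, the pΩ-Ala frequency comparison with Fisher's exact test for
a named allotype pair, C1-vs-C2 enrichment volcano tables at pΩ and
pΩ-1, the unique/shared decomposition of the pair with position-wise
Pearson correlations, and the residue-volume correlation at pΩ-1.

``run_geometry_analysis`` measures the four groove descriptors over a
manifest of coordinate files and compares C1 vs C2 with Welch t-tests.

Reports are plain CSV plus one JSON summary; all randomness is seeded
and outputs are byte-stable for a fixed config (the run log carries the
only timestamp).
"""

from __future__ import annotations

import csv as _csv
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .allotypes import AllotypeRecord, Group, lookup_allotype, read_allotype_table
from .alphabet import AMINO_ACIDS, MAX_LENGTH, MIN_LENGTH, is_valid_peptide
from .contaminants import ContaminantMotif, filter_contaminant_motifs
from .enrichment import group_enrichment, positionwise_correlation, volume_correlation
from .peptides import PeptideSet, merge_datasets, partition_unique_shared, peptide_set
from .pfm import position_frequency_matrix, residue_frequency
from .stats import fisher_count_test
from .volumes import VolumeTable

log = logging.getLogger(__name__)

REPORT_SCHEMAS = {
    "pomega_frequency": ["allotype", "group", "length", "aa", "count", "total", "percent"],
    "volcano": [
        "aa", "mean_c1", "mean_c2", "sd_c1", "sd_c2", "mean_c1_pc", "mean_c2_pc",
        "fold_c2_c1", "log2_fold", "p_student", "p_welch", "q_bh", "significant",
    ],
    "correlations": ["position", "n_unique_a", "n_unique_b", "pearson_r"],
    "volume_correlation": ["aa", "volume", "log2_fold"],
    "descriptors": [
        "structure_id", "group", "d77_pomega1", "d_tyr171_nterm", "d_val76_side",
        "omega_term", "psi_pomega1",
    ],
    "group_stats": ["descriptor", "n_c1", "n_c2", "mean_c1", "sd_c1", "mean_c2", "sd_c2", "p_welch"],
}


def validate_report(df: pd.DataFrame, schema: str) -> None:
    expected = REPORT_SCHEMAS[schema]
    if list(df.columns) != expected:
        raise ValueError(f"report {schema!r} columns {list(df.columns)} != schema {expected}")


@dataclass
class RunConfig:
    """Configuration for a pipeline run; round-trips through YAML."""

    peptide_files: list[str] = field(default_factory=list)  # CSVs: allotype,peptide[,source]
    allotype_table: str | None = None                       # CSV name,res77,res80 (else bundled)
    structure_manifest: str | None = None                   # CSV for the geometry arm
    pair: tuple[str, str] = ("C*08:02", "C*05:01")
    length: int = 9
    analyses: dict = field(
        default_factory=lambda: {
            "pomega": True, "pomega1": True, "unique_shared": True, "volume": True,
        }
    )
    pseudocount: float = 0.5
    t_test: str = "student"
    out_dir: str = "results"
    seed: int = 0
    fetch: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        if isinstance(cfg.pair, list):
            cfg.pair = tuple(cfg.pair)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["pair"] = list(self.pair)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def validate(self) -> list[str]:
        """Collect all validation problems before any computation."""
        problems = []
        for p in self.peptide_files:
            if not Path(p).exists():
                problems.append(f"peptide file not found: {p}")
        for p in (self.allotype_table, self.structure_manifest):
            if p and not Path(p).exists():
                problems.append(f"file not found: {p}")
        if not MIN_LENGTH <= self.length <= MAX_LENGTH:
            problems.append(f"length {self.length} outside {MIN_LENGTH}-{MAX_LENGTH}")
        if self.t_test not in ("student", "welch"):
            problems.append(f"unknown t_test {self.t_test!r}")
        if self.pseudocount < 0:
            problems.append("pseudocount must be >= 0")
        return problems


class ConfigError(ValueError):
    pass


def _read_panel(config: RunConfig) -> tuple[dict[str, PeptideSet], dict]:
    """Read and merge all peptide files; return per-allotype sets + accounting."""
    lookup: dict[str, AllotypeRecord] = {}
    if config.allotype_table:
        lookup = {r.name: r for r in read_allotype_table(config.allotype_table)}

    def _lookup(name: str) -> AllotypeRecord:
        if name in lookup:
            return lookup[name]
        try:
            return lookup_allotype(name)
        except KeyError as exc:
            raise ConfigError(str(exc)) from None

    per_file_sets: dict[str, list[PeptideSet]] = {}
    accounting = {"rows_read": {}, "length_dropped": {}, "duplicates_removed": {}, "kept": {}}
    for path in config.peptide_files:
        raw: dict[str, list[str]] = {}
        with open(path, newline="") as fh:
            reader = _csv.DictReader(fh)
            if reader.fieldnames is None or not {"allotype", "peptide"} <= set(reader.fieldnames):
                raise ConfigError(f"{path}: expected CSV columns allotype,peptide")
            for lineno, row in enumerate(reader, start=2):
                seq = row["peptide"].strip().upper()
                if not is_valid_peptide(seq):
                    raise ConfigError(f"{path}:{lineno}: invalid peptide {seq!r}")
                raw.setdefault(row["allotype"].strip(), []).append(seq)
        for name, seqs in raw.items():
            in_range = [s for s in seqs if MIN_LENGTH <= len(s) <= MAX_LENGTH]
            acc = accounting
            acc["rows_read"][name] = acc["rows_read"].get(name, 0) + len(seqs)
            acc["length_dropped"][name] = (
                acc["length_dropped"].get(name, 0) + len(seqs) - len(in_range)
            )
            acc["duplicates_removed"][name] = (
                acc["duplicates_removed"].get(name, 0) + len(in_range) - len(set(in_range))
            )
            per_file_sets.setdefault(name, []).append(
                peptide_set(_lookup(name), in_range, source=Path(path).name)
            )
    sets: dict[str, PeptideSet] = {}
    for name, pieces in per_file_sets.items():
        merged = merge_datasets(pieces)
        # cross-file duplicates fold into the same accounting bucket
        accounting["duplicates_removed"][name] += sum(len(p) for p in pieces) - len(merged)
        accounting["kept"][name] = len(merged)
        sets[name] = merged
    return sets, accounting


def run_peptidome_analysis(
    config: RunConfig, contaminant_motifs: list[ContaminantMotif] | None = None
) -> dict:
    """Run the sequence arm end to end; returns a summary dict.

    Writes per-allotype PFMs, the pΩ frequency/Fisher table for the
    configured pair, volcano tables at pΩ and pΩ-1, unique/shared
    correlations, the volume correlation, and a machine-readable run
    log accounting for every input peptide.
    """
    problems = config.validate()
    if problems:
        raise ConfigError("; ".join(problems))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    L = config.length

    sets, accounting = _read_panel(config)
    accounting["contaminant_removed"] = {}
    if contaminant_motifs:
        for name in sorted(sets):
            filtered, removed = filter_contaminant_motifs(sets[name], contaminant_motifs)
            sets[name] = filtered
            accounting["contaminant_removed"][name] = len(removed)
            accounting["kept"][name] = len(filtered)

    pfms = {}
    for name in sorted(sets):
        stratum = sets[name].stratum(L)
        if len(stratum) == 0:
            log.warning("%s: no %dmers; excluded from motif analysis", name, L)
            continue
        pfms[name] = position_frequency_matrix(stratum, L)
        pfms[name].to_frame().to_csv(out / f"pfm_{name.replace('*', '').replace(':', '')}.csv")

    summary: dict = {"n_allotypes": len(pfms), "length": L, "outputs": {}}

    # pΩ frequency table + Fisher comparison for the configured pair
    rows = []
    for name, pfm in sorted(pfms.items()):
        rec = sets[name].allotype
        for aa in AMINO_ACIDS:
            count = int(pfm.count_row(L)[AMINO_ACIDS.index(aa)])
            rows.append(
                {
                    "allotype": name, "group": rec.group.value, "length": L, "aa": aa,
                    "count": count, "total": pfm.n,
                    "percent": 100.0 * count / pfm.n,
                }
            )
    freq_df = pd.DataFrame(rows, columns=REPORT_SCHEMAS["pomega_frequency"])
    validate_report(freq_df, "pomega_frequency")
    freq_df.to_csv(out / "pomega_frequency.csv", index=False)
    summary["outputs"]["pomega_frequency"] = "pomega_frequency.csv"

    a_name, b_name = config.pair
    if a_name in sets and b_name in sets:
        ka, na, pa = residue_frequency(sets[a_name], L, L, "A")
        kb, nb, pb = residue_frequency(sets[b_name], L, L, "A")
        p_fisher = fisher_count_test(ka, na, kb, nb)
        summary["pomega_ala_pair"] = {
            "allotype_a": a_name, "count_a": ka, "total_a": na, "percent_a": pa,
            "allotype_b": b_name, "count_b": kb, "total_b": nb, "percent_b": pb,
            "fisher_p": p_fisher,
        }

    panel = [(sets[name].allotype, pfm) for name, pfm in sorted(pfms.items())]
    n_c1 = sum(1 for rec, _ in panel if rec.group is Group.C1)
    n_c2 = sum(1 for rec, _ in panel if rec.group is Group.C2)
    enough_groups = n_c1 >= 2 and n_c2 >= 2

    volume_source = None
    for toggle, position, label in (("pomega", L, "pOmega"), ("pomega1", L - 1, "pOmega1")):
        if not config.analyses.get(toggle, True):
            continue
        if not enough_groups:
            log.warning("fewer than 2 allotypes per group; skipping %s volcano", label)
            continue
        table = group_enrichment(panel, position, config.pseudocount, config.t_test)
        df = table.table[REPORT_SCHEMAS["volcano"]]
        validate_report(df, "volcano")
        df.to_csv(out / f"volcano_{label}.csv", index=False)
        summary["outputs"][f"volcano_{label}"] = f"volcano_{label}.csv"
        summary[f"flagged_{label}"] = table.flagged()
        if toggle == "pomega1":
            volume_source = table

    if config.analyses.get("unique_shared", True) and a_name in sets and b_name in sets:
        ua, ub, shared = partition_unique_shared(sets[a_name], sets[b_name], L)
        corr_a, corr_b = ua, ub
        if not (ua and ub):
            # fully (or one-sidedly) overlapping repertoires: correlate the
            # whole strata instead of the empty unique fractions
            log.warning("empty unique fraction; correlating full %dmer strata", L)
            corr_a = frozenset(p for p in sets[a_name].peptides if len(p) == L)
            corr_b = frozenset(p for p in sets[b_name].peptides if len(p) == L)
        if corr_a and corr_b:
            pfm_a = position_frequency_matrix(corr_a, L)
            pfm_b = position_frequency_matrix(corr_b, L)
            corr_rows = []
            for pos in range(1, L + 1):
                try:
                    r = positionwise_correlation(pfm_a, pfm_b, pos)
                except ValueError:
                    r = float("nan")
                corr_rows.append(
                    {"position": pos, "n_unique_a": len(corr_a), "n_unique_b": len(corr_b), "pearson_r": r}
                )
            corr_df = pd.DataFrame(corr_rows, columns=REPORT_SCHEMAS["correlations"])
            validate_report(corr_df, "correlations")
            corr_df.to_csv(out / "unique_shared_correlations.csv", index=False)
            summary["outputs"]["unique_shared_correlations"] = "unique_shared_correlations.csv"
            summary["unique_shared"] = {
                "unique_a": len(ua), "unique_b": len(ub), "shared": len(shared),
            }

    if config.analyses.get("volume", True) and volume_source is not None:
        r, scatter = volume_correlation(volume_source, VolumeTable())
        validate_report(scatter, "volume_correlation")
        scatter.to_csv(out / "volume_correlation.csv", index=False)
        summary["outputs"]["volume_correlation"] = "volume_correlation.csv"
        summary["volume_correlation_r"] = r

    run_log = {
        "version": __version__,
        "seed": config.seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "accounting": accounting,
        "summary": summary,
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=2, sort_keys=True)
    return summary


def run_geometry_analysis(config: RunConfig) -> dict:
    """Run the structure arm over a manifest of coordinate files.

    Manifest columns: structure_id, path (or accession with
    ``fetch: true``), group (C1/C2), and optional heavy_chain /
    peptide_chain overrides.  Unparseable rows are recorded and the run
    continues; the summary reports per-row failures.
    """
    from .geometry import GeometryRecord, fetch_pdb, group_geometry_stats, load_structure, measure_structure

    problems = config.validate()
    if problems:
        raise ConfigError("; ".join(problems))
    if not config.structure_manifest:
        raise ConfigError("no structure_manifest configured")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest = pd.read_csv(config.structure_manifest, dtype=str).fillna("")
    required = {"structure_id", "path", "group"}
    if not required <= set(manifest.columns):
        raise ConfigError(f"manifest needs columns {sorted(required)}")

    records: list[GeometryRecord] = []
    failures: list[dict] = []
    for _, row in manifest.iterrows():
        sid = row["structure_id"]
        try:
            path = row["path"]
            if not Path(path).exists() and config.fetch:
                path = str(fetch_pdb(sid, Path(config.out_dir) / "structures"))
            model = load_structure(
                path,
                heavy_chain=row.get("heavy_chain") or None,
                peptide_chain=row.get("peptide_chain") or None,
                group=row["group"] or None,
                structure_id=sid,
            )
            records.append(measure_structure(model))
        except Exception as exc:  # per-row isolation: one bad file must not kill the run
            log.error("%s: %s", sid, exc)
            failures.append({"structure_id": sid, "error": str(exc)})

    summary: dict = {"n_structures": len(records), "failures": failures, "outputs": {}}
    if not records:
        raise ConfigError("all manifest rows failed to parse")

    desc_df = pd.DataFrame([r.as_dict() for r in records], columns=REPORT_SCHEMAS["descriptors"])
    validate_report(desc_df, "descriptors")
    desc_df.to_csv(out / "geometry_descriptors.csv", index=False)
    summary["outputs"]["descriptors"] = "geometry_descriptors.csv"

    groups = desc_df["group"].value_counts().to_dict()
    if groups.get("C1", 0) >= 2 and groups.get("C2", 0) >= 2:
        stats_df = group_geometry_stats(records)
        validate_report(stats_df, "group_stats")
        stats_df.to_csv(out / "geometry_group_stats.csv", index=False)
        summary["outputs"]["group_stats"] = "geometry_group_stats.csv"
        summary["group_stats"] = stats_df.set_index("descriptor")[
            ["mean_c1", "sd_c1", "mean_c2", "sd_c2", "p_welch"]
        ].to_dict("index")
    else:
        log.warning("fewer than 2 structures per group; skipping group statistics")
        summary["group_stats"] = None

    with open(out / "geometry_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    return summary
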