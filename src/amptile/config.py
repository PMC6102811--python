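"""Run parameters: one YAML file drives every stage of the pipeline.

Unknown keys are rejected, defaults are those of the owning modules, and
an effective-parameter hash is written into each stage manifest so any
artifact can be traced to the exact configuration that produced it.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from amptile.errors import ConfigError

log = logging.getLogger("amptile")

DEFAULTS: dict[str, dict[str, Any]] = {
    "paths": {
        "subreads": None,
        "ccs": None,
        "panel": None,
        "reference": None,
        "out_dir": "amptile_out",
    },
    "clustering": {
        "search_space": None,   # resolved to 21 (one-level) / 121 (two-level)
        "two_level": False,
        "include_padding": True,
        "max_mismatch": 0,
    },
    "ccs": {
        "min_passes": 1,
        "min_predicted_accuracy": 0.90,
    },
    "consensus": {
        "min_subreads": 100,
        "min_subread_length": 0,
        "max_iters": 5,
    },
    "assembly": {
        "trim_bp": None,        # default: panel barcode+padding length
        "min_overlap": 40,
        "min_identity": 0.94,
    },
    "evaluate": {
        "depths": list(range(1, 41)),
        "replicates": 25,
        "seed": 0,
    },
}

_NUMERIC_BOUNDS = {
    ("clustering", "search_space"): (1, None),
    ("clustering", "max_mismatch"): (0, None),
    ("ccs", "min_passes"): (1, None),
    ("ccs", "min_predicted_accuracy"): (0.0, 1.0),
    ("consensus", "min_subreads"): (0, None),
    ("consensus", "min_subread_length"): (0, None),
    ("consensus", "max_iters"): (1, None),
    ("assembly", "trim_bp"): (0, None),
    ("assembly", "min_overlap"): (1, None),
    ("assembly", "min_identity"): (0.0, 1.0),
    ("evaluate", "replicates"): (1, None),
    ("evaluate", "seed"): (0, None),
}


@dataclass
class RunParameters:
    sections: dict[str, dict[str, Any]] = field(default_factory=lambda: copy.deepcopy(DEFAULTS))

    def __getitem__(self, section: str) -> dict[str, Any]:
        return self.sections[section]

    def effective_search_space(self) -> int:
        ss = self.sections["clustering"]["search_space"]
        if ss is not None:
            return ss
        return 121 if self.sections["clustering"]["two_level"] else 21

    def params_hash(self) -> str:
        blob = json.dumps(self.sections, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _validate_sections(data: dict) -> None:
    for section, keys in data.items():
        if section not in DEFAULTS:
            raise ConfigError(f"unknown config section: {section!r}")
        if keys is None:
            continue
        if not isinstance(keys, dict):
            raise ConfigError(f"section {section!r} must be a mapping")
        for key in keys:
            if key not in DEFAULTS[section]:
                raise ConfigError(f"unknown config key: {section}.{key}")


def load_params(path: Optional[str | Path] = None,
                overrides: Optional[dict[str, Any]] = None) -> RunParameters:
    """Load a run-parameters file (missing values filled with defaults).

    ``overrides`` takes dotted 'section.key' entries, mirroring CLI
    --set flags.  Raises ConfigError naming the offending key on any
    unknown or out-of-range value.
    """
    data: dict = {}
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        loaded = yaml.safe_load(path.read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError("config root must be a mapping")
        data = loaded
    _validate_sections(data)

    params = RunParameters()
    for section, keys in data.items():
        if keys:
            params.sections[section].update(keys)
    for dotted, value in (overrides or {}).items():
        if "." not in dotted:
            raise ConfigError(f"override {dotted!r} must be 'section.key'")
        section, key = dotted.split(".", 1)
        if section not in DEFAULTS or key not in DEFAULTS[section]:
            raise ConfigError(f"unknown config key: {dotted}")
        params.sections[section][key] = value

    for (section, key), (lo, hi) in _NUMERIC_BOUNDS.items():
        v = params.sections[section][key]
        if v is None:
            continue
        if not isinstance(v, (int, float)) or isinstance(v, bool):
            raise ConfigError(f"{section}.{key} must be numeric, got {v!r}")
        if (lo is not None and v < lo) or (hi is not None and v > hi):
            raise ConfigError(f"{section}.{key}={v} outside [{lo}, {hi}]")

    panel_path = params.sections["paths"]["panel"]
    if panel_path is not None and Path(panel_path).exists():
        from amptile.panel import PrimerPanel
        panel = PrimerPanel.from_tsv(panel_path)
        if params.sections["clustering"]["two_level"] and not panel.barcoded:
            raise ConfigError("clustering.two_level=true but the panel has no barcodes")
        if not params.sections["clustering"]["two_level"] and panel.barcoded:
            raise ConfigError("panel has barcodes but clustering.two_level=false")
    log.info("effective parameters: %s", json.dumps(params.sections, default=str))
    return params


def _write_manifest(out_dir: Path, stage: str, params: RunParameters,
                    inputs: dict, outputs: dict) -> None:
    manifest = {
        "stage": stage,
        "params_hash": params.params_hash(),
        "inputs": {k: str(v) for k, v in inputs.items()},
        "outputs": {k: str(v) for k, v in outputs.items()},
    }
    (out_dir / f"manifest.{stage}.json").write_text(json.dumps(manifest, indent=2) + "\n")


def run_all(params: RunParameters) -> dict[str, Any]:
    """Execute ccs -> cluster -> consensus -> assemble (-> evaluate when a
    reference is configured) from a subreads FASTQ and a panel TSV.

    Returns a summary dict of per-stage artifacts; raises with the
    failing stage named.
    """
    from amptile import io as aio
    from amptile.assembly import assemble_sample
    from amptile.ccs import build_ccs_batch
    from amptile.cluster import cluster_ccs, write_whitelists
    from amptile.consensus import consensus_all
    from amptile.panel import PrimerPanel
    from amptile.simulate import ReferenceSet

    paths = params.sections["paths"]
    for required in ("subreads", "panel"):
        if paths[required] is None or not Path(paths[required]).exists():
            raise ConfigError(f"paths.{required} is missing or does not exist")
    out_dir = Path(paths["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out_dir / "run.log")
    log.addHandler(fh)
    summary: dict[str, Any] = {}
    try:
        panel = PrimerPanel.from_tsv(paths["panel"])
        raw_reads = aio.read_subreads_fastq(paths["subreads"])
        raw_by_mol = {r.molecule_id: r for r in raw_reads}

        stage = "ccs"
        log.info("stage %s: %d molecules", stage, len(raw_reads))
        if paths["ccs"] is not None and Path(paths["ccs"]).exists():
            ccs_reads, rejections = aio.read_ccs_fastq(paths["ccs"]), []
        else:
            ccs_reads, rejections = build_ccs_batch(
                raw_reads,
                min_passes=params["ccs"]["min_passes"],
                min_predicted_accuracy=params["ccs"]["min_predicted_accuracy"])
        ccs_path = aio.write_ccs_fastq(ccs_reads, rejections, out_dir / "ccs.fastq",
                                       sidecar=out_dir / "ccs_report.tsv")
        _write_manifest(out_dir, stage, params,
                        {"subreads": paths["subreads"]}, {"ccs": ccs_path})
        summary["n_ccs"] = len(ccs_reads)

        stage = "cluster"
        cmap = cluster_ccs(ccs_reads, panel,
                           search_space=params.effective_search_space(),
                           two_level=params["clustering"]["two_level"],
                           include_padding=params["clustering"]["include_padding"],
                           max_mismatch=params["clustering"]["max_mismatch"])
        for c in rejections:
            cmap.unassigned.append((c.molecule_id, "filtered"))
        counts = {r.molecule_id: r.n_passes for r in raw_reads}
        wl_dir = out_dir / "whitelists"
        write_whitelists(cmap, wl_dir, subread_counts=counts)
        _write_manifest(out_dir, stage, params, {"ccs": ccs_path}, {"whitelists": wl_dir})
        summary["n_assigned"] = len(cmap.assignments)
        summary["n_unassigned"] = len(cmap.unassigned)

        stage = "consensus"
        records = consensus_all(cmap.clusters(), raw_by_mol,
                                min_subreads=params["consensus"]["min_subreads"],
                                min_subread_length=params["consensus"]["min_subread_length"],
                                panel=panel,
                                max_iters=params["consensus"]["max_iters"])
        cons_path = aio.write_fasta(
            {r.name: r.sequence for r in records if r.status == "emitted"},
            out_dir / "consensus.fasta")
        aio.write_tsv([{"sample_id": r.cluster_id[0] or "", "amplicon_id": r.cluster_id[1],
                        "n_molecules": r.n_molecules, "n_subreads": r.n_subreads,
                        "status": r.status, "iterations": r.iterations} for r in records],
                      out_dir / "consensus_report.tsv",
                      ["sample_id", "amplicon_id", "n_molecules", "n_subreads",
                       "status", "iterations"])
        _write_manifest(out_dir, stage, params, {"whitelists": wl_dir},
                        {"consensus": cons_path})
        summary["n_consensus"] = sum(1 for r in records if r.status == "emitted")

        stage = "assemble"
        trim_bp = params["assembly"]["trim_bp"]
        if trim_bp is None:
            e0 = panel.entries[0]
            trim_bp = len(e0.padding) + len(e0.barcode)
        asm_dir = out_dir / "assembly"
        samples = panel.sample_ids or [None]
        assemblies = {}
        for sample in samples:
            assemblies[sample] = assemble_sample(
                records, trim_bp=trim_bp,
                min_overlap=params["assembly"]["min_overlap"],
                min_identity=params["assembly"]["min_identity"],
                sample_id=sample, out_dir=asm_dir)
        _write_manifest(out_dir, stage, params, {"consensus": cons_path},
                        {"assembly": asm_dir})
        summary["assemblies"] = {
            str(s): [c.contig_id for c in a.contigs] for s, a in assemblies.items()}

        if paths["reference"] is not None and Path(paths["reference"]).exists():
            stage = "evaluate"
            from amptile.evaluate import align_and_report
            ref = ReferenceSet.from_fasta(paths["reference"])
            rows = []
            for r in records:
                if r.status != "emitted":
                    continue
                rep = align_and_report(r.sequence, ref, query_id=r.name)
                rows.append({"query_id": rep.query_id, "locus_id": rep.locus_id or "",
                             "percent_identity": f"{rep.percent_identity:.4f}",
                             "n_mismatch": rep.n_mismatch,
                             "n_insertion_bases": rep.n_insertion_bases,
                             "n_deletion_bases": rep.n_deletion_bases,
                             "classification": rep.classification})
            rep_path = aio.write_tsv(rows, out_dir / "alignment_reports.tsv",
                                     ["query_id", "locus_id", "percent_identity",
                                      "n_mismatch", "n_insertion_bases",
                                      "n_deletion_bases", "classification"],
                                     comment="local alignment of emitted consensus "
                                             "sequences against the reference")
            _write_manifest(out_dir, stage, params, {"consensus": cons_path},
                            {"reports": rep_path})
            summary["n_reports"] = len(rows)
    except Exception as exc:
        log.error("stage %s failed: %s", stage, exc)
        raise
    finally:
        log.removeHandler(fh)
        fh.close()
    return summary
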