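"""End-to-end orchestration: call -> enumerate -> select, plus immunomonitoring.

``run_genomics`` chains the somatic caller, effect annotation, RNA support,
peptide enumeration and vaccine selection from files on disk;
``run_monitoring`` runs the ELISpot and TCR analyses.  ``demo`` generates a
fully synthetic patient with planted truth and runs everything, so the
whole pipeline is reproducible from a single seed.

Every output file starts with comment lines recording the tool version and
the full parameter set, and a structured run log (stage/key/value rows)
records the variant count surviving each filter stage.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from . import __version__
from . import elispot_analysis as ea
from . import epitope_selection as es
from . import peptide_enumeration as pe
from . import somatic_calling as sc
from . import synthetic_data as sd
from . import tcr_repertoire as tr


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and input."""


def _params_comment(label: str, params) -> str:
    if dataclasses.is_dataclass(params):
        params = dataclasses.asdict(params)
    body = " ".join(f"{k}={v}" for k, v in sorted(params.items()))
    return f"# neovax {__version__} {label}: {body}\n"


def _write_with_header(df: pd.DataFrame, path: Path, label: str, params) -> None:
    with open(path, "w") as fh:
        fh.write(_params_comment(label, params))
        df.to_csv(fh, sep="\t", index=False)


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


class RunLog:
    """Structured (stage, key, value) log; filter counts are parseable."""

    def __init__(self) -> None:
        self.rows: list[tuple[str, str, str]] = []

    def add(self, stage: str, key: str, value) -> None:
        self.rows.append((stage, key, str(value)))

    def write(self, path: Path) -> None:
        df = pd.DataFrame(self.rows, columns=["stage", "key", "value"])
        with open(path, "w") as fh:
            fh.write(f"# neovax {__version__} run log\n")
            df.to_csv(fh, sep="\t", index=False)


def run_genomics(
    pileup_path,
    annotation_path,
    fasta_path,
    rna_path,
    affinity_path,
    out_dir,
    caller_params: sc.CallerParams | None = None,
    selection_params: es.SelectionParams | None = None,
    affinity_dialect: str = "generic_tsv",
) -> pd.DataFrame:
    """Somatic calling through vaccine selection; returns the selection frame.

    Writes calls.tsv, calls.vcf, candidates.tsv, selection.tsv and
    run_log.tsv under ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    caller_params = caller_params or sc.CallerParams()
    selection_params = selection_params or es.SelectionParams()
    log = RunLog()

    def _stage(name: str, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    sites = _stage("read_pileup", pd.read_csv, pileup_path, sep="\t", comment="#")
    log.add("input", "n_sites", len(sites))
    annotation = _stage("read_annotation", pd.read_csv, annotation_path, sep="\t", comment="#")
    cds = _stage("read_fasta", read_fasta, fasta_path)
    rna = _stage("read_rna", pd.read_csv, rna_path, sep="\t", comment="#")
    affinities = _stage("read_affinity", es.read_affinity_table, affinity_path, affinity_dialect)

    calls = _stage("call_variants", sc.call_variants, sites, caller_params)
    log.add("call_variants", "n_calls", len(calls))
    calls = _stage("annotate", sc.annotate_variants, calls, annotation, cds) if len(calls) else calls
    if len(calls):
        calls = calls[calls["effect"] == "missense"].reset_index(drop=True)
    log.add("annotate", "n_missense", len(calls))
    calls = _stage("rna_support", sc.rna_support, calls, rna)
    log.add("rna_support", "n_expressed", int(calls["expressed"].sum()) if len(calls) else 0)

    _write_with_header(calls, out_dir / "calls.tsv", "caller", caller_params)
    sc.write_vcf(calls, out_dir / "calls.vcf")

    contexts = _stage("contexts", pe.contexts_from_calls, calls, cds) if len(calls) else []
    candidates: list[pe.PeptideCandidate] = []
    for ctx in contexts:
        candidates.extend(pe.enumerate_candidates(ctx, cls="I"))
        candidates.extend(pe.enumerate_candidates(ctx, cls="II"))
    log.add("enumerate", "n_candidates", len(candidates))
    _write_with_header(
        pe.candidates_to_frame(candidates), out_dir / "candidates.tsv", "enumeration",
        {"classI_lengths": pe.CLASS_I_LENGTHS, "classII_lengths": pe.CLASS_II_LENGTHS},
    )

    selection = _stage(
        "select", es.select_vaccine_peptides, candidates, affinities, calls, selection_params
    )
    log.add("select", "n_selected", len(selection))
    frame = es.selection_to_frame(selection)
    _write_with_header(frame, out_dir / "selection.tsv", "selection", selection_params)
    log.write(out_dir / "run_log.tsv")
    return frame


def run_monitoring(
    out_dir,
    plate_path=None,
    control_condition: str = sd.CONTROL_CONDITION,
    elispot_threshold: float = ea.DEFAULT_THRESHOLD,
    tcr_pre_path=None,
    tcr_post_path=None,
    tcr_threshold: float = tr.DISPLAY_THRESHOLD,
) -> dict:
    """ELISpot positivity and/or TCR repertoire comparison from files.

    Either analysis is skipped (and logged) when its input is absent.
    Writes elispot_results.tsv, tcr_report.tsv and tcr_summary.json.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log = RunLog()
    summary: dict = {}

    if plate_path is not None:
        plate = ea.read_plate_csv(plate_path)
        wells = ea.wells_from_frame(plate)
        results, counts = ea.call_positivity(wells, control_condition, elispot_threshold)
        df = ea.results_to_frame(results, counts)
        for k, v in counts.items():
            df.attrs.setdefault("counts", {})
            log.add("elispot", k, v)
        _write_with_header(
            df, out_dir / "elispot_results.tsv", "elispot",
            {"control": control_condition, "threshold": elispot_threshold},
        )
        summary["elispot_counts"] = counts
    else:
        log.add("elispot", "skipped", "no plate input")

    if tcr_pre_path is not None and tcr_post_path is not None:
        pre = tr.ClonotypeTable.from_tsv(tcr_pre_path, sample_id="pre")
        post = tr.ClonotypeTable.from_tsv(tcr_post_path, sample_id="post")
        cmp = tr.compare(pre, post, threshold=tcr_threshold)
        df, payload = tr.comparison_report(cmp)
        _write_with_header(df, out_dir / "tcr_report.tsv", "tcr", {"threshold": tcr_threshold})
        (out_dir / "tcr_summary.json").write_text(payload + "\n")
        log.add("tcr", "n_emergent", len(cmp.emergent))
        summary["tcr"] = json.loads(payload)
    else:
        log.add("tcr", "skipped", "no clonotype inputs")

    log.write(out_dir / "monitoring_log.tsv")
    return summary


# ---------------------------------------------------------------------------
# synthetic end-to-end demo
# ---------------------------------------------------------------------------

def _plant_nested_binder(
    candidates: list[pe.PeptideCandidate],
    class_i_alleles: list[str],
    class_ii_alleles: list[str],
) -> dict[tuple[str, str], float]:
    """Plant one strong class II / nested class I pair among the candidates.

    The first variant owning both a class II candidate and a class I
    candidate contained in it gets IC50s of 2 nM (class II) and 5 nM
    (class I) -- below any plausible hash-derived competitor.
    """
    by_variant: dict[tuple[str, str], dict[str, list[pe.PeptideCandidate]]] = {}
    for c in candidates:
        by_variant.setdefault((c.gene, c.aa_change), {"I": [], "II": []})[c.cls].append(c)
    for key in sorted(by_variant):
        for ii in by_variant[key]["II"]:
            for i in by_variant[key]["I"]:
                if i.peptide in ii.peptide:
                    return {
                        (ii.peptide, class_ii_alleles[0]): 2.0,
                        (i.peptide, class_i_alleles[0]): 5.0,
                    }
    return {}


def demo(seed: int, out_dir, config: sd.SimulationConfig | None = None) -> dict:
    """Generate a synthetic patient and run the full pipeline on it.

    Returns a summary dict with the planted truth and the paths written.
    Problem sizes default to a few hundred candidate sites so the demo
    completes in seconds.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = config or sd.SimulationConfig(seed=seed, n_sites=300, n_transcripts=40)

    sites, truth = sd.gen_tumour_normal_counts(config)
    cds, annotation, rna = sd.gen_transcriptome(config, truth)
    plate, planted_positives = sd.gen_elispot_plate(config)
    pre, post, expanded_truth = sd.gen_clonotype_tables(config)

    inputs = out_dir / "inputs"
    inputs.mkdir(exist_ok=True)
    sd.write_pileup_tsv(sites, inputs / "pileup.tsv")
    sd.write_annotation_tsv(annotation, inputs / "annotation.tsv")
    sd.write_fasta(cds, inputs / "transcripts.fa")
    sd.write_rna_tsv(rna, inputs / "rna_counts.tsv")
    sd.write_elispot_csv(plate, inputs / "plate.csv")
    sd.write_clonotype_tsv(pre, inputs / "tcr_pre.tsv")
    sd.write_clonotype_tsv(post, inputs / "tcr_post.tsv")

    # affinity table over all candidate peptides, with one planted nested pair
    calls = sc.call_variants(sites)
    calls = sc.annotate_variants(calls, annotation, cds) if len(calls) else calls
    if len(calls):
        calls = calls[calls["effect"] == "missense"]
    contexts = pe.contexts_from_calls(calls, cds) if len(calls) else []
    candidates: list[pe.PeptideCandidate] = []
    for ctx in contexts:
        candidates.extend(pe.enumerate_candidates(ctx, cls="I"))
        candidates.extend(pe.enumerate_candidates(ctx, cls="II"))
    class_i, class_ii = sd.default_hla_alleles(config)
    planted_pair = _plant_nested_binder(candidates, class_i, class_ii)
    peptides_i = sorted({c.peptide for c in candidates if c.cls == "I"})
    peptides_ii = sorted({c.peptide for c in candidates if c.cls == "II"})
    affinity = pd.concat([
        sd.build_affinity_table(peptides_i, class_i, seed=config.seed, planted=planted_pair),
        sd.build_affinity_table(peptides_ii, class_ii, seed=config.seed, planted=planted_pair),
    ], ignore_index=True)
    affinity.to_csv(inputs / "affinity.tsv", sep="\t", index=False)

    selection = run_genomics(
        inputs / "pileup.tsv", inputs / "annotation.tsv", inputs / "transcripts.fa",
        inputs / "rna_counts.tsv", inputs / "affinity.tsv", out_dir,
    )
    monitoring = run_monitoring(
        out_dir, plate_path=inputs / "plate.csv",
        tcr_pre_path=inputs / "tcr_pre.tsv", tcr_post_path=inputs / "tcr_post.tsv",
    )
    return {
        "out_dir": str(out_dir),
        "n_truth_sites": len(truth),
        "planted_pair": {f"{p}|{a}": v for (p, a), v in planted_pair.items()},
        "planted_elispot_positives": planted_positives,
        "planted_expanded_clonotypes": sorted(expanded_truth),
        "n_selected": len(selection),
        "monitoring": monitoring,
    }


def run_from_config(config_path) -> dict:
    """Run genomics and/or monitoring from a flat YAML run configuration.

    Recognised keys: pileup, annotation, fasta, rna, affinity,
    affinity_dialect, out_dir, plate, control_condition, elispot_threshold,
    tcr_pre, tcr_post, tcr_threshold, plus any CallerParams/SelectionParams
    field under ``caller.<field>`` / ``selection.<field>``.
    """
    cfg = yaml.safe_load(Path(config_path).read_text()) or {}
    out_dir = cfg.get("out_dir", "neovax_out")
    caller_kwargs = {k.split(".", 1)[1]: v for k, v in cfg.items() if k.startswith("caller.")}
    sel_kwargs = {k.split(".", 1)[1]: v for k, v in cfg.items() if k.startswith("selection.")}
    summary: dict = {}
    if all(cfg.get(k) for k in ("pileup", "annotation", "fasta", "rna", "affinity")):
        frame = run_genomics(
            cfg["pileup"], cfg["annotation"], cfg["fasta"], cfg["rna"], cfg["affinity"],
            out_dir,
            caller_params=sc.CallerParams(**caller_kwargs),
            selection_params=es.SelectionParams(**sel_kwargs),
            affinity_dialect=cfg.get("affinity_dialect", "generic_tsv"),
        )
        summary["n_selected"] = len(frame)
    summary["monitoring"] = run_monitoring(
        out_dir,
        plate_path=cfg.get("plate"),
        control_condition=cfg.get("control_condition", sd.CONTROL_CONDITION),
        elispot_threshold=float(cfg.get("elispot_threshold", ea.DEFAULT_THRESHOLD)),
        tcr_pre_path=cfg.get("tcr_pre"),
        tcr_post_path=cfg.get("tcr_post"),
        tcr_threshold=float(cfg.get("tcr_threshold", tr.DISPLAY_THRESHOLD)),
    )
    return summary
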