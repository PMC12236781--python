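"""Pipeline configuration and stage orchestration.

``run_pipeline`` wires the stages together over a directory of input files
(the layout the synthetic generator produces, or equivalently named real
data): screening -> super calling -> the downstream analyses enabled in the
config. Each stage writes a TSV report into the output directory; runs are
deterministic for a fixed config and seed.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import cgi as cgi_mod
from . import conversion as conv_mod
from . import cooperativity as coop_mod
from . import genes as genes_mod
from . import screening, supercall
from . import tads as tads_mod
from . import variants as var_mod
from .intervals import Element, IntervalIndex, merge_overlapping
from .io import read_bedgraph, read_bedpe, read_genes, read_intervals

logger = logging.getLogger("supersil")

ALL_STAGES = ("screen", "supercall", "coop", "assoc", "variants", "tad", "convert", "cgi")


class ConfigurationError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Paths, parameters and stage toggles for one pipeline run.

    Parameter defaults equal the method's stated values: 1 kb windows with
    100 bp steps, FPR 0.1, 12.5 kb stitch distance, 50 kb variant flank,
    10 kb contact bins with >80 kb spans.
    """

    input_dir: str = "."
    output_dir: str = "out"
    stages: list = field(default_factory=lambda: list(ALL_STAGES))
    seed: int = 0

    window: int = 1_000
    step: int = 100
    fpr: float = 0.1
    stitch_distance: int = 12_500
    promoter_flank: int = 2_000
    variant_flank: int = 50_000
    contact_bin: int = 10_000
    contact_min_span: int = 80_000
    cgi_min_overlap: int = 200
    locus_flank: int = 50_000

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise ConfigurationError(f"stage {stage!r} requires missing input: {path}")
    return path


def run_pipeline(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Execute the enabled stages in order and write per-stage TSV reports.

    Returns the report tables keyed by stage name. Missing inputs for an
    enabled stage raise :class:`ConfigurationError` before any computation.
    """
    indir = Path(config.input_dir)
    outdir = Path(config.output_dir)
    stages = [s for s in ALL_STAGES if s in config.stages]
    unknown = set(config.stages) - set(ALL_STAGES)
    if unknown:
        raise ConfigurationError(f"unknown stages: {sorted(unknown)}")

    # fail fast on missing inputs
    needs = {
        "screen": ["h3k27me3_peaks.narrowPeak", "h3k27ac_peaks.narrowPeak",
                   "dnase_peaks.bed", "background_peaks.bed",
                   "h3k27me3.bedGraph", "h3k27ac.bedGraph"],
        "supercall": [], "coop": ["activity_by_cell"], "assoc": ["genes.tsv", "expression.tsv"],
        "variants": ["snv.tsv", "tlbp.tsv"], "tad": ["tad_boundaries.bed"],
        "convert": ["cancer_se"], "cgi": ["cgi.bed", "contacts.bedpe"],
    }
    downstream = {"supercall", "coop", "assoc", "variants", "tad", "convert", "cgi"}
    if (set(stages) & downstream) and "screen" not in stages:
        raise ConfigurationError("downstream stages require the 'screen' stage")
    for stage in stages:
        for name in needs[stage]:
            _require(indir / name, stage)

    reports: dict[str, pd.DataFrame] = {}
    if not stages:
        return reports
    outdir.mkdir(parents=True, exist_ok=True)

    state: dict = {}
    for stage in stages:
        logger.info("running stage %s", stage)
        reports[stage] = _STAGE_FUNCS[stage](config, indir, state)
        reports[stage].to_csv(outdir / f"{stage}.tsv", sep="\t", index=False)
    return reports


def _screen(config: PipelineConfig, indir: Path, state: dict) -> pd.DataFrame:
    activity = read_intervals(indir / "dnase_peaks.bed")
    bg_peaks = read_intervals(indir / "background_peaks.bed")
    rows = []
    for mark, peaks_file, track_file in (
            ("repressive", "h3k27me3_peaks.narrowPeak", "h3k27me3.bedGraph"),
            ("active", "h3k27ac_peaks.narrowPeak", "h3k27ac.bedGraph")):
        peaks = [e.interval for e in read_intervals(indir / peaks_file, format="narrowPeak")]
        track = read_bedgraph(indir / track_file)
        scorer = screening.SignalMeanScorer(track)
        bg_windows = []
        for p in bg_peaks:
            bg_windows.extend(screening.tile_windows(p, config.window, config.step))
        elements, threshold = screening.screen_peaks(
            peaks, activity, scorer, bg_windows=bg_windows, fpr=config.fpr,
            window=config.window, step=config.step)
        elements = [dataclasses.replace(e, name=f"{mark[:3]}{i:05d}")
                    for i, e in enumerate(elements)]
        state[f"elements_{mark}"] = elements
        state[f"track_{mark}"] = track
        for e in elements:
            rows.append({"mark": mark, "chrom": e.chrom, "start": e.start, "end": e.end,
                         "name": e.name, "score": e.score, "ts": threshold.ts})
    return pd.DataFrame(rows)


def _supercall(config: PipelineConfig, indir: Path, state: dict) -> pd.DataFrame:
    rows = []
    for mark, super_cls, typ_cls in (("repressive", "SS_component", "TS"),
                                     ("active", "SE_component", "TE")):
        regions, cutoff = supercall.call_super_regions(
            state[f"elements_{mark}"], state[f"track_{mark}"],
            stitch_distance=config.stitch_distance,
            super_class=super_cls, typical_class=typ_cls)
        state[f"regions_{mark}"] = regions
        for r in regions:
            rows.append({"mark": mark, "chrom": r.chrom, "start": r.interval.start,
                         "end": r.interval.end, "n_components": r.n_members,
                         "signal": r.total_signal, "rank": r.rank,
                         "is_super": r.is_super, "cutoff": cutoff})
    state["elements_by_class"] = _classified_elements(state)
    return pd.DataFrame(rows)


def _classified_elements(state: dict) -> dict[str, list[Element]]:
    by_class: dict[str, list[Element]] = {"SS_component": [], "TS": [],
                                          "SE_component": [], "TE": []}
    for mark in ("repressive", "active"):
        for region in state.get(f"regions_{mark}", []):
            for el in region.members:
                by_class[el.element_class].append(el)
    return by_class


def _coop(config: PipelineConfig, indir: Path, state: dict) -> pd.DataFrame:
    cells_dir = indir / "activity_by_cell"
    ac_by_cell, me_by_cell = {}, {}
    for f in sorted(cells_dir.glob("*.h3k27ac.bed")):
        ac_by_cell[f.name.split(".")[0]] = read_intervals(f)
    for f in sorted(cells_dir.glob("*.h3k27me3.bed")):
        me_by_cell[f.name.split(".")[0]] = read_intervals(f)
    by_class = state["elements_by_class"]
    all_elements = [el for els in by_class.values() for el in els]
    matrix = coop_mod.build_activity_matrix(all_elements, ac_by_cell, me_by_cell)
    state["activity_matrix"] = matrix

    rows = []
    for mark, super_cls, ts_cls in (("repressive", "SS_component", "TS"),
                                    ("active", "SE_component", "TE")):
        super_regions = [r for r in state[f"regions_{mark}"] if r.is_super and r.n_members >= 2]
        pairs = []
        for region in super_regions:
            pairs.extend(itertools.combinations(region.members, 2))
        bg_pairs, kept_pairs = coop_mod.matched_background_pairs(
            pairs, by_class[ts_cls], seed=config.seed)

        def _pair_scores(pair_list):
            out = []
            for a, b in pair_list:
                s = coop_mod.cooperativity(
                    matrix.loc[a.name or f"{a.chrom}:{a.start}-{a.end}"].to_numpy(),
                    matrix.loc[b.name or f"{b.chrom}:{b.start}-{b.end}"].to_numpy())
                if s is not None:
                    out.append(s)
            return out

        within = _pair_scores(kept_pairs)
        bg = _pair_scores(bg_pairs)
        p = (float(stats.ranksums(within, bg, alternative="greater").pvalue)
             if within and bg else np.nan)
        rows.append({"mark": mark, "n_within_pairs": len(within),
                     "mean_within": float(np.mean(within)) if within else np.nan,
                     "n_background_pairs": len(bg),
                     "mean_background": float(np.mean(bg)) if bg else np.nan,
                     "ranksum_p_greater": p})
    return pd.DataFrame(rows)


def _assoc(config: PipelineConfig, indir: Path, state: dict) -> pd.DataFrame:
    genes = read_genes(indir / "genes.tsv", indir / "expression.tsv")
    state["genes"] = genes
    expression = {g.gene_id: g.expression for g in genes}
    assoc_by_class = {}
    for cls, els in state["elements_by_class"].items():
        assoc_by_class[cls] = [a for a in (genes_mod.nearest_gene(el, genes) for el in els)
                               if a is not None]
    state["associations_by_class"] = assoc_by_class
    return genes_mod.class_expression_summary(assoc_by_class, expression)


def _variants(config: PipelineConfig, indir: Path, state: dict) -> pd.DataFrame:
    snvs = var_mod.read_variant_table(indir / "snv.tsv", kind="somatic_SNV")
    tlbps = var_mod.read_variant_table(indir / "tlbp.tsv", kind="TLBP")
    state["snvs"], state["tlbps"] = snvs, tlbps
    by_class = state["elements_by_class"]
    bcell = [v for v in snvs if v.variant_class == "B_cell_cancer"]
    rows = []
    for cls, els in by_class.items():
        if not els:
            continue
        inside = var_mod.variants_in(snvs, els)
        rows.append({
            "element_class": cls,
            "bcell_snv_density_per_kb": var_mod.density_per_kb(bcell, els),
            "bcell_fraction": var_mod.class_fraction(inside, "B_cell_cancer"),
            "recurrent_fraction": var_mod.recurrent_fraction(
                [v for v in inside if v.variant_class == "B_cell_cancer"]),
            "n_snvs_in": len(inside),
            "n_tlbp_in": sum(1 for lbl in var_mod.proximal_partition(tlbps, els,
                                                                     config.variant_flank)
                             if lbl == "in"),
        })
    return pd.DataFrame(rows)


def _tad(config: PipelineConfig, indir: Path, state: dict) -> pd.DataFrame:
    bounds = tads_mod.boundaries_from_intervals(read_intervals(indir / "tad_boundaries.bed"))
    state["boundaries"] = bounds
    sizes = {c: int(arr.max() + 2_000_000) for c, arr in bounds.items()}
    if (Path(indir) / "manifest.yaml").exists():
        sizes = yaml.safe_load((indir / "manifest.yaml").read_text())["chrom_sizes"]
    return tads_mod.segment_enrichment(state["elements_by_class"], bounds, sizes)


def _convert(config: PipelineConfig, indir: Path, state: dict) -> pd.DataFrame:
    by_class = state["elements_by_class"]
    rows = []
    for src_dir, source_classes in (("cancer_se", ("SS_component", "TS", "TE")),
                                    ("cancer_ss", ("SE_component",))):
        d = indir / src_dir
        if not d.exists():
            continue
        per_sample = {f.stem: read_intervals(f) for f in sorted(d.glob("*.bed"))}
        sources = [el for cls in source_classes for el in by_class[cls]]
        records = conv_mod.detect_conversions(sources, per_sample)
        state.setdefault("conversion_records", []).extend(records)
        for direction in sorted({r.direction for r in records}):
            recs = [r for r in records if r.direction == direction]
            n_src = sum(len(by_class[c]) for c in source_classes
                        if conv_mod.CONVERSION_DIRECTIONS.get(c) == direction)
            n_rec = sum(1 for r in recs if r.recurrent)
            rows.append({"direction": direction, "n_converted": len(recs),
                         "n_source_elements": n_src,
                         "converted_fraction": len(recs) / n_src if n_src else np.nan,
                         "recurrent_fraction": n_rec / len(recs) if recs else np.nan})
    return pd.DataFrame(rows)


def _cgi(config: PipelineConfig, indir: Path, state: dict) -> pd.DataFrame:
    cgis = merge_overlapping(read_intervals(indir / "cgi.bed"))
    cgi_index = IntervalIndex(cgis)
    contacts = read_bedpe(indir / "contacts.bedpe", bin_size=config.contact_bin,
                          min_span=config.contact_min_span)
    by_class = state["elements_by_class"]
    subclasses: dict[str, list[Element]] = {}
    for cls, els in by_class.items():
        if cls == "SS_component":
            for el in els:
                c = cgi_mod.classify_cgi(el, cgi_index, config.cgi_min_overlap)
                subclasses.setdefault(
                    "CGI_SS" if c.is_cgi else "nonCGI_SS", []).append(el)
        else:
            subclasses[cls] = list(els)
    state["cgi_subclasses"] = subclasses
    density = cgi_mod.element_contact_density(subclasses, contacts)
    anchor_index = cgi_mod.AnchorIndex(contacts)
    flank_rows = []
    for cls, els in subclasses.items():
        vals = [cgi_mod.flank_contact_enrichment(el, contacts, index=anchor_index)
                for el in els]
        flank_rows.append({"element_class": cls,
                           "mean_flank_contacts_per_10kb":
                               float(np.mean(vals)) if vals else np.nan})
    return density.merge(pd.DataFrame(flank_rows), on="element_class")


_STAGE_FUNCS = {
    "screen": _screen, "supercall": _supercall, "coop": _coop, "assoc": _assoc,
    "variants": _variants, "tad": _tad, "convert": _convert, "cgi": _cgi,
}
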