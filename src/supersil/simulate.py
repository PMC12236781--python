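"""Synthetic epigenome generator with planted ground truth.

Emulates every input the analysis consumes on a small two-chromosome genome:
repressive/active mark peaks and signal tracks, per-cell-type activity peaks,
TF ChIP-seq peaks, CpG islands, per-CpG methylation, genes with per-cell-type
expression, TAD boundaries, chromatin contacts (normal and cancer), somatic
SNVs, translocation breakpoints, GWAS SNPs with LD pairs, and per-sample
cancer super-region calls. Every planted object is recorded exactly in a
truth manifest serialized next to the outputs, so each downstream stage can
be scored against known ground truth.

Default parameters mirror the study conditions the method targets: ~1.5 kb
elements, super clusters of 5 components spanning ~36 kb, heavy-tailed
(log-normal) mark signal, 27% CGI super-silencer components, a 10% shore
placement rate, class-proportional somatic variant rates (SS:TS:TE:SE =
0.50:0.38:0.33:0.81), 13% of super-silencer clusters converting to cancer
super-enhancers, and contact structure with CGI-dependent density. Variant
densities are scaled up from genome-wide per-kb values so class ratios are
measurable on a 40 Mb genome; see the methods note.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .intervals import GenomicInterval

__all__ = ["TruthManifest", "GenerationError", "simulate_all",
           "simulate_epigenome", "simulate_variants", "simulate_contacts"]


class GenerationError(RuntimeError):
    """Raised when planted objects cannot be placed on the synthetic genome."""


@dataclass
class TruthManifest:
    """All generator parameters plus exact records of planted objects."""

    seed: int = 0
    chrom_sizes: dict = field(default_factory=lambda: {"chr1": 20_000_000, "chr2": 20_000_000})
    cell_types: list = field(default_factory=lambda: (
        ["stem_like", "differentiated"] + [f"cell{i:02d}" for i in range(10)]))
    reference_cell: str = "differentiated"

    # planted element architecture
    n_ss_clusters: int = 20
    n_se_clusters: int = 20
    components_per_cluster: int = 5
    cluster_span: int = 36_000
    n_ts: int = 150
    n_te: int = 150
    n_bg_peaks: int = 300
    element_length: int = 1_500

    # mark signal (log-normal, arbitrary track units)
    ts_signal_mean: float = 2.0
    ss_ts_signal_ratio: float = 8.0
    bg_signal_mean: float = 0.5
    signal_sigma: float = 0.25  # log-scale sd

    # cross-cell-type activity
    activity_correlation: float = 0.8

    # CGIs and methylation
    cgi_fraction_ss: float = 0.27
    cgi_length: int = 800
    meth_mean_ss: float = 0.10
    meth_mean_other: float = 0.45

    # TADs
    tad_spacing: int = 2_000_000
    ss_shore_probability: float = 0.10

    # variants (per-kb rates inside elements; B-cell cancer class)
    snv_rate_per_kb: dict = field(default_factory=lambda: {
        "SS_component": 0.50, "SE_component": 0.81, "TS": 0.38, "TE": 0.33})
    snv_rate_scale: float = 20.0
    bg_snv_rate_per_kb: float = 0.29  # non-element accessible background
    other_cancer_snv_rate_per_kb: float = 4.0  # uniform inside elements, both classes
    recurrent_fraction: dict = field(default_factory=lambda: {
        "SS_component": 0.035, "SE_component": 0.063, "TS": 0.0175, "TE": 0.0175})
    n_bcell_tlbp: int = 250
    tlbp_shore_fraction: float = 0.48
    tlbp_se_partner_fraction: float = 0.26
    n_gwas_snps: int = 300
    gwas_replicated_fraction_ss: float = 0.78
    gwas_replicated_fraction_other: float = 0.35

    # conversions and cancer samples
    conversion_fraction_ss: float = 0.13
    conversion_fraction_se: float = 0.05
    n_cancer_samples: int = 6
    conversion_detection_prob: float = 0.6

    # contacts
    contact_bin: int = 10_000
    contact_min_span: int = 80_000
    contacts_per_element: float = 6.0
    cgi_contact_ratio: float = 2.0
    flank_contacts_per_10kb: float = 5.0
    noncgi_ss_flank_factor: float = 0.15
    promoter_contacts_mean: float = 3.0
    promoter_enhancer_contact_prob: float = 0.5
    conversion_contact_drop: float = 0.91
    background_contact_drop: float = 0.2

    # genes and expression
    gene_spacing: int = 100_000
    base_expression_mean: float = 10.0
    expression_sigma: float = 0.5
    ss_stem_factor: float = 3.0
    ss_differentiated_factor: float = 1.0 / 3.0
    conversion_expression_fold: float = 9.8
    jq1_down_prob: dict = field(default_factory=lambda: {
        "SS_to_SE": 0.4, "SE": 0.15, "other": 0.03})

    # filled by the generator
    truth: dict = field(default_factory=dict)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data.pop("truth")
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "TruthManifest":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def rng(self, role: str) -> np.random.Generator:
        """Deterministic substream per file role: enabling one output never
        shifts another."""
        return np.random.default_rng([self.seed, zlib.crc32(role.encode()) % (2**31)])

    @property
    def ss_signal_mean(self) -> float:
        return self.ts_signal_mean * self.ss_ts_signal_ratio


def _lognormal(rng, mean: float, sigma: float, size=None):
    mu = np.log(mean) - sigma**2 / 2.0
    return rng.lognormal(mu, sigma, size=size)


# ---------------------------------------------------------------------------
# placement


class _Placer:
    """Tracks occupied intervals per chromosome; rejects colliding placements."""

    def __init__(self, chrom_sizes: dict, margin: int = 100_000, separation: int = 15_000):
        self.sizes = dict(chrom_sizes)
        self.margin = margin
        self.separation = separation
        self.occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_sizes}

    def free(self, chrom: str, start: int, end: int) -> bool:
        if start < self.margin or end > self.sizes[chrom] - self.margin:
            return False
        for s, e in self.occupied[chrom]:
            if start < e + self.separation and end > s - self.separation:
                return False
        return True

    def claim(self, chrom: str, start: int, end: int) -> None:
        self.occupied[chrom].append((start, end))

    def place(self, rng, length: int, chrom: str | None = None,
              start_window: tuple[str, int, int] | None = None,
              max_tries: int = 500) -> tuple[str, int, int]:
        """Claim a free interval; ``start_window`` constrains the start
        position to ``[lo, hi]`` on the named chromosome."""
        chroms = list(self.sizes)
        for _ in range(max_tries):
            if start_window is not None:
                c, lo, hi = start_window
                if hi < lo:
                    break
                s = int(rng.integers(lo, hi + 1))
            else:
                c = chrom or chroms[int(rng.integers(len(chroms)))]
                s = int(rng.integers(self.margin, self.sizes[c] - self.margin - length))
            if self.free(c, s, s + length):
                self.claim(c, s, s + length)
                return c, s, s + length
        raise GenerationError("cannot place object: genome too crowded")


# ---------------------------------------------------------------------------
# epigenome


def _tad_boundaries(m: TruthManifest) -> dict[str, list[int]]:
    rng = m.rng("tads")
    out = {}
    for chrom, size in m.chrom_sizes.items():
        positions = []
        p = m.tad_spacing
        while p < size - m.tad_spacing // 2:
            positions.append(int(p + rng.integers(-100_000, 100_000)))
            p += m.tad_spacing
        out[chrom] = positions
    return out


def _plant_cluster_binned(rng, placer: _Placer, m: TruthManifest) -> list[dict]:
    """Place one super cluster with one component per 10 kb contact bin,
    centered inside its bin, so each component owns its anchor bin."""
    k, L, B = m.components_per_cluster, m.element_length, m.contact_bin
    claim = (k + 1) * B + B  # room for bin snapping
    chrom, start, end = placer.place(rng, claim)
    first_bin = ((start // B) + 1) * B
    offset = (B - L) // 2
    return [{"chrom": chrom, "start": first_bin + i * B + offset,
             "end": first_bin + i * B + offset + L} for i in range(k)]


def _plant_cluster_compact(rng, placer: _Placer, m: TruthManifest,
                           start_window: tuple[str, int, int]) -> list[dict]:
    """Place one compact cluster (6 kb pitch) inside a constrained window,
    used for shore-resident clusters that must fit a 30 kb shore."""
    k, L = m.components_per_cluster, m.element_length
    pitch = 6_000
    span = (k - 1) * pitch + L
    chrom, start, end = placer.place(rng, span, start_window=start_window)
    return [{"chrom": chrom, "start": start + i * pitch,
             "end": start + i * pitch + L} for i in range(k)]


def simulate_epigenome(manifest: TruthManifest, outdir) -> dict:
    """Generate mark peaks, signal tracks, activity peaks per cell type, TF
    peaks, CGIs, methylation, genes + expression, and TAD boundaries.

    Returns (and stores on ``manifest.truth``) the planted ground truth.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    m = manifest
    placer = _Placer(m.chrom_sizes)
    boundaries = _tad_boundaries(m)

    rng = m.rng("layout")
    truth: dict = {"boundaries": boundaries, "elements": []}

    # shore-resident clusters use a compact span so every component midpoint
    # stays 20-50 kb from the boundary
    shore_span = (m.components_per_cluster - 1) * 6_000 + m.element_length
    shore_windows = []
    for chrom, bs in boundaries.items():
        for b in bs:
            # start windows keeping the whole cluster inside [21k, 49k] of b
            shore_windows.append((chrom, b + 21_000, b + 49_000 - shore_span))
            shore_windows.append((chrom, b - 49_000, b - 21_000 - shore_span))
    shore_windows = [(c, lo, hi) for c, lo, hi in shore_windows if hi >= lo]

    def far_from_boundaries(chrom, start, end) -> bool:
        mid = (start + end) // 2
        bs = boundaries[chrom]
        return all(abs(mid - b) > 60_000 for b in bs)

    elements = []  # dict records
    eid = 0

    def record(chrom, start, end, cls, cluster=None, shore=False):
        nonlocal eid
        rec = {"id": f"el{eid:05d}", "chrom": chrom, "start": int(start), "end": int(end),
               "class": cls, "cluster": cluster, "shore": bool(shore)}
        eid += 1
        elements.append(rec)
        return rec

    for kind, n_clusters in (("SS", m.n_ss_clusters), ("SE", m.n_se_clusters)):
        for ci in range(n_clusters):
            on_shore = (kind == "SS") and (rng.random() < m.ss_shore_probability)
            if on_shore:
                comps = None
                for _ in range(50):
                    window = shore_windows[int(rng.integers(len(shore_windows)))]
                    try:
                        comps = _plant_cluster_compact(rng, placer, m, window)
                        break
                    except GenerationError:
                        continue
                if comps is None:
                    raise GenerationError("no free shore window for a shore cluster")
            else:
                for _ in range(200):
                    comps = _plant_cluster_binned(rng, placer, m)
                    if all(far_from_boundaries(c["chrom"], c["start"], c["end"])
                           for c in comps):
                        break
                    # too close to a boundary: release and retry
                    placer.occupied[comps[0]["chrom"]].pop()
                else:
                    raise GenerationError("cannot place cluster away from boundaries")
            for c in comps:
                record(c["chrom"], c["start"], c["end"], f"{kind}_component",
                       cluster=f"{kind.lower()}{ci:03d}", shore=on_shore)

    # typical elements are placed in loose groups of three (silencers and
    # enhancers cluster at the tens-of-kb scale), giving the background pool
    # pairs at the same distances as super-cluster component pairs
    L = m.element_length
    for cls, n in (("TS", m.n_ts), ("TE", m.n_te)):
        placed = 0
        while placed < n:
            group = min(3, n - placed)
            gaps = [int(rng.integers(15_000, 28_000)) for _ in range(group - 1)]
            total = group * L + sum(gaps)
            chrom, s, _ = placer.place(rng, total)
            pos = s
            for i in range(group):
                record(chrom, pos, pos + L, cls)
                placed += 1
                if i < group - 1:
                    pos += L + gaps[i]

    bg_peaks = []
    for _ in range(m.n_bg_peaks):
        chrom, s, e = placer.place(rng, m.element_length)
        bg_peaks.append({"chrom": chrom, "start": s, "end": e})

    # exact per-component shore status from the realized geometry
    for r in elements:
        mid = (r["start"] + r["end"]) // 2
        d = min(abs(mid - b) for b in boundaries[r["chrom"]])
        r["shore"] = bool(20_000 < d <= 50_000)

    # signal values
    sig_rng = m.rng("signal")
    for rec in elements:
        mean = {"SS_component": m.ss_signal_mean, "TS": m.ts_signal_mean,
                "SE_component": m.ss_signal_mean, "TE": m.ts_signal_mean}[rec["class"]]
        rec["signal_value"] = float(_lognormal(sig_rng, mean, m.signal_sigma))
    bg_values = _lognormal(sig_rng, m.bg_signal_mean, m.signal_sigma, size=len(bg_peaks))

    silencers = [r for r in elements if r["class"] in ("SS_component", "TS")]
    enhancers = [r for r in elements if r["class"] in ("SE_component", "TE")]

    def write_peaks(path, recs, scores=None):
        with open(path, "w") as fh:
            for i, r in enumerate(sorted(recs, key=lambda x: (x["chrom"], x["start"]))):
                score = r.get("signal_value", 0.0) if scores is None else scores[i]
                fh.write(f"{r['chrom']}\t{r['start']}\t{r['end']}\t{r.get('id', f'bg{i}')}"
                         f"\t0\t.\t{score:.4f}\t-1\t-1\t-1\n")

    # repressive/active mark peaks: planted elements plus low-signal decoys
    bg_half = bg_peaks[:len(bg_peaks) // 2]
    bg_half2 = bg_peaks[len(bg_peaks) // 2:]
    write_peaks(out / "h3k27me3_peaks.narrowPeak", silencers + bg_half)
    write_peaks(out / "h3k27ac_peaks.narrowPeak", enhancers + bg_half2)

    # activity (accessibility) peaks: every planted element and decoy is open
    with open(out / "dnase_peaks.bed", "w") as fh:
        for r in sorted(elements + bg_peaks, key=lambda x: (x["chrom"], x["start"])):
            fh.write(f"{r['chrom']}\t{r['start']}\t{r['end']}\n")

    # background calibration windows (the decoy peaks, labeled)
    with open(out / "background_peaks.bed", "w") as fh:
        for r in sorted(bg_peaks, key=lambda x: (x["chrom"], x["start"])):
            fh.write(f"{r['chrom']}\t{r['start']}\t{r['end']}\n")

    # signal tracks
    def write_track(path, recs, decoys, decoy_values):
        segs = []
        for r in recs:
            segs.append((r["chrom"], r["start"], r["end"], r["signal_value"]))
        for r, v in zip(decoys, decoy_values):
            segs.append((r["chrom"], r["start"], r["end"], float(v)))
        segs.sort()
        with open(path, "w") as fh:
            for chrom, s, e, v in segs:
                fh.write(f"{chrom}\t{s}\t{e}\t{v:.4f}\n")

    write_track(out / "h3k27me3.bedGraph", silencers, bg_half, bg_values[:len(bg_half)])
    write_track(out / "h3k27ac.bedGraph", enhancers, bg_half2, bg_values[len(bg_half):])

    # per-cell-type activity peaks (for the activity matrix)
    act_rng = m.rng("activity")
    state_by_cell: dict[str, dict[str, int]] = {c: {} for c in m.cell_types}
    marginal = np.array([0.55, 0.35, 0.10])  # P(-1), P(+1), P(0) for silencers

    def draw_state(sign: int) -> int:
        u = act_rng.random()
        if sign < 0:
            return -1 if u < marginal[0] else (1 if u < marginal[0] + marginal[1] else 0)
        return 1 if u < marginal[0] else (-1 if u < marginal[0] + marginal[1] else 0)

    clusters: dict[str, list[dict]] = {}
    for r in elements:
        if r["cluster"]:
            clusters.setdefault(r["cluster"], []).append(r)

    latent = {cl: {} for cl in clusters}
    for cl, members in clusters.items():
        sign = -1 if members[0]["class"] == "SS_component" else 1
        for cell in m.cell_types:
            latent[cl][cell] = draw_state(sign)
    for r in elements:
        sign = -1 if r["class"] in ("SS_component", "TS") else 1
        for cell in m.cell_types:
            if cell == m.reference_cell:
                state = -1 if sign < 0 else 1
            elif r["cluster"]:
                state = (latent[r["cluster"]][cell]
                         if act_rng.random() < m.activity_correlation
                         else draw_state(sign))
            else:
                state = draw_state(sign)
            state_by_cell[cell][r["id"]] = state

    cells_dir = out / "activity_by_cell"
    cells_dir.mkdir(exist_ok=True)
    by_id = {r["id"]: r for r in elements}
    for cell in m.cell_types:
        me_recs, ac_recs = [], []
        for el_id, state in state_by_cell[cell].items():
            r = by_id[el_id]
            if state == -1:
                me_recs.append(r)
            elif state == 1:
                ac_recs.append(r)
            else:  # uncertain: both marks
                me_recs.append(r)
                ac_recs.append(r)
        for mark, recs in (("h3k27me3", me_recs), ("h3k27ac", ac_recs)):
            with open(cells_dir / f"{cell}.{mark}.bed", "w") as fh:
                for r in sorted(recs, key=lambda x: (x["chrom"], x["start"])):
                    fh.write(f"{r['chrom']}\t{r['start']}\t{r['end']}\n")
    truth["activity_states"] = {c: dict(state_by_cell[c]) for c in m.cell_types}

    # TF ChIP-seq peaks: cluster-preferred TFs bind multiple components
    tf_rng = m.rng("tfbs")
    n_tfs = 40
    tf_names = [f"TF{i:02d}" for i in range(n_tfs)]
    binding: dict[str, list[dict]] = {tf: [] for tf in tf_names}
    for cl, members in clusters.items():
        preferred = [tf for tf in tf_names if tf_rng.random() < 0.15]
        for tf in preferred:
            for r in members:
                if tf_rng.random() < 0.6:
                    binding[tf].append(r)
    for tf in tf_names:
        bound_ids = {r["id"] for r in binding[tf]}
        for r in elements:
            if r["id"] not in bound_ids and tf_rng.random() < 0.05:
                binding[tf].append(r)
    tf_dir = out / "tf_peaks"
    tf_dir.mkdir(exist_ok=True)
    for tf in tf_names:
        with open(tf_dir / f"{tf}.bed", "w") as fh:
            for r in sorted(binding[tf], key=lambda x: (x["chrom"], x["start"])):
                fh.write(f"{r['chrom']}\t{r['start']}\t{r['end']}\n")

    # CGIs: a chosen fraction of SS components overlap a CGI well past 200 bp
    cgi_rng = m.rng("cgi")
    cgis = []
    ss_recs = [r for r in elements if r["class"] == "SS_component"]
    for r in ss_recs:
        r["cgi"] = bool(cgi_rng.random() < m.cgi_fraction_ss)
        if r["cgi"]:
            s = r["start"] + int(cgi_rng.integers(0, r["end"] - r["start"] - m.cgi_length))
            cgis.append((r["chrom"], s, s + m.cgi_length))
    for r in elements:
        r.setdefault("cgi", False)
    with open(out / "cgi.bed", "w") as fh:
        for chrom, s, e in sorted(cgis):
            fh.write(f"{chrom}\t{s}\t{e}\n")

    # methylation: a few CpG sites per element, SS components hypomethylated
    meth_rng = m.rng("methylation")
    with open(out / "methylation.bedGraph", "w") as fh:
        for r in sorted(elements, key=lambda x: (x["chrom"], x["start"])):
            mean = m.meth_mean_ss if r["class"] == "SS_component" else m.meth_mean_other
            for i in range(3):
                pos = r["start"] + 200 + i * 400
                v = float(np.clip(meth_rng.normal(mean, 0.05), 0.0, 1.0))
                fh.write(f"{r['chrom']}\t{pos}\t{pos + 1}\t{v:.4f}\n")

    # genes and expression
    gene_rng = m.rng("genes")
    genes = []
    gi = 0
    for chrom, size in m.chrom_sizes.items():
        p = 150_000
        while p < size - 150_000:
            tss = p + int(gene_rng.integers(-20_000, 20_000))
            genes.append({"gene_id": f"G{gi:04d}", "chrom": chrom,
                          "start": tss, "end": tss + 20_000, "strand": "+", "tss": tss})
            gi += 1
            p += m.gene_spacing

    # nearest planted object per gene decides its expression program
    def nearest_class(g):
        best, best_d = None, None
        for r in elements:
            if r["chrom"] != g["chrom"]:
                continue
            d = abs(((r["start"] + r["end"]) // 2) - g["tss"])
            if best_d is None or d < best_d:
                best, best_d = r, d
        return (best, best_d) if best_d is not None and best_d < 60_000 else (None, None)

    expr_rows = []
    for g in genes:
        near, _ = nearest_class(g)
        base = float(_lognormal(gene_rng, m.base_expression_mean, m.expression_sigma))
        row = {"gene_id": g["gene_id"]}
        for cell in m.cell_types:
            level = base * float(_lognormal(gene_rng, 1.0, m.expression_sigma))
            if near is not None and near["class"] == "SS_component":
                if cell == "stem_like":
                    level *= m.ss_stem_factor
                elif cell == m.reference_cell:
                    level *= m.ss_differentiated_factor
            row[cell] = round(level, 4)
        g["nearest_class"] = near["class"] if near else "none"
        g["nearest_cluster"] = near["cluster"] if near else None
        expr_rows.append(row)

    with open(out / "genes.tsv", "w") as fh:
        fh.write("gene_id\tchrom\tstart\tend\tstrand\ttss\n")
        for g in genes:
            fh.write(f"{g['gene_id']}\t{g['chrom']}\t{g['start']}\t{g['end']}"
                     f"\t{g['strand']}\t{g['tss']}\n")
    with open(out / "expression.tsv", "w") as fh:
        fh.write("gene_id\t" + "\t".join(m.cell_types) + "\n")
        for row in expr_rows:
            fh.write(row["gene_id"] + "\t"
                     + "\t".join(f"{row[c]:g}" for c in m.cell_types) + "\n")

    # TAD boundary BED (10 kb intervals whose midpoints are the boundaries)
    with open(out / "tad_boundaries.bed", "w") as fh:
        for chrom in sorted(boundaries):
            for b in boundaries[chrom]:
                fh.write(f"{chrom}\t{b - 5_000}\t{b + 5_000}\n")

    # conversions: individual SS components become cancer SE regions (and the
    # reverse for SE components), each detected independently per sample
    conv_rng = m.rng("conversion")
    ss_ids = [r["id"] for r in elements if r["class"] == "SS_component"]
    se_ids = [r["id"] for r in elements if r["class"] == "SE_component"]
    se_clusters = sorted({r["cluster"] for r in elements if r["class"] == "SE_component"})
    ss_clusters = sorted({r["cluster"] for r in elements if r["class"] == "SS_component"})
    n_conv_ss = max(1, round(m.conversion_fraction_ss * len(ss_ids)))
    n_conv_se = max(1, round(m.conversion_fraction_se * len(se_ids)))
    conv_ss = sorted(conv_rng.choice(ss_ids, size=n_conv_ss, replace=False).tolist())
    conv_se = sorted(conv_rng.choice(se_ids, size=n_conv_se, replace=False).tolist())

    def cluster_span_of(cl):
        members = clusters[cl]
        return (members[0]["chrom"], min(r["start"] for r in members),
                max(r["end"] for r in members))

    samples = [f"sample{i:02d}" for i in range(m.n_cancer_samples)]
    detected: dict[str, dict[str, bool]] = {}
    for conv_set, dirname in ((conv_ss, "cancer_se"), (conv_se, "cancer_ss")):
        d = out / dirname
        d.mkdir(exist_ok=True)
        # non-conversion decoys: cancer supers over same-sign normal clusters
        same_sign = se_clusters if dirname == "cancer_se" else ss_clusters
        for sample in samples:
            rows = []
            for el_id in conv_set:
                hit = bool(conv_rng.random() < m.conversion_detection_prob)
                detected.setdefault(el_id, {})[sample] = hit
                if hit:
                    r = by_id[el_id]
                    rows.append((r["chrom"], r["start"], r["end"]))
            for cl in same_sign:
                if conv_rng.random() < 0.8:  # stable cancer supers of the same sign
                    rows.append(cluster_span_of(cl))
            with open(d / f"{sample}.bed", "w") as fh:
                for chrom, s, e in sorted(rows):
                    fh.write(f"{chrom}\t{s}\t{e}\n")

    # cancer expression: genes of conversion-hosting clusters upregulated
    conv_ss_clusters = {by_id[i]["cluster"] for i in conv_ss}
    conv_gene_rows = []
    for g, row in zip(genes, expr_rows):
        normal = row[m.reference_cell]
        fold = (m.conversion_expression_fold
                if g["nearest_cluster"] in conv_ss_clusters else 1.0)
        cancer = normal * fold * float(_lognormal(conv_rng, 1.0, 0.1))
        conv_gene_rows.append((g["gene_id"], normal, round(cancer, 4)))
    with open(out / "cancer_expression.tsv", "w") as fh:
        fh.write("gene_id\tnormal\tcancer\n")
        for gid, nrm, can in conv_gene_rows:
            fh.write(f"{gid}\t{nrm:g}\t{can:g}\n")

    # JQ1-style treatment time course
    jq1_rng = m.rng("jq1")
    tc_rows = []
    for g in genes:
        if g["nearest_cluster"] in conv_ss_clusters:
            cls = "SS_to_SE"
        elif g["nearest_class"] == "SE_component":
            cls = "SE"
        else:
            cls = "other"
        g["jq1_class"] = cls
        responds = jq1_rng.random() < m.jq1_down_prob[cls]
        base = 10.0
        for tp in (2, 6, 24):
            shift = -4.0 if responds else 0.0
            for cond in ("control", "treated"):
                for rep in range(3):
                    v = base + (shift if cond == "treated" else 0.0) \
                        + float(jq1_rng.normal(0, 0.5))
                    tc_rows.append((g["gene_id"], tp, cond, rep, round(v, 4)))
    with open(out / "jq1_timecourse.tsv", "w") as fh:
        fh.write("gene\ttimepoint\tcondition\treplicate\tvalue\n")
        for r in tc_rows:
            fh.write("\t".join(str(x) for x in r) + "\n")

    truth.update({
        "elements": elements,
        "bg_peaks": bg_peaks,
        "genes": genes,
        "conversions_ss": conv_ss,
        "conversions_se": conv_se,
        "conversion_detected": detected,
        "clusters": {cl: [r["id"] for r in members] for cl, members in clusters.items()},
    })
    manifest.truth = truth
    return truth


# ---------------------------------------------------------------------------
# variants


def simulate_variants(manifest: TruthManifest, outdir) -> None:
    """Generate somatic SNVs, translocation breakpoints and GWAS SNP + LD
    tables over the planted elements (requires simulate_epigenome first)."""
    m = manifest
    if not m.truth:
        raise GenerationError("epigenome must be generated before variants")
    out = Path(outdir)
    rng = m.rng("variants")
    elements = m.truth["elements"]

    snv_rows = []
    vid = 0
    bg_records = [dict(r, **{"class": "background"}) for r in m.truth["bg_peaks"]]
    for r in elements + bg_records:
        kb = (r["end"] - r["start"]) / 1_000
        rate = m.snv_rate_per_kb.get(r["class"], m.bg_snv_rate_per_kb) * m.snv_rate_scale
        f_rec = m.recurrent_fraction.get(r["class"], 0.0)
        for _ in range(int(rng.poisson(rate * kb))):
            pos = int(rng.integers(r["start"], r["end"]))
            n_donors = 2 if rng.random() < f_rec else 1
            for d in range(n_donors):
                snv_rows.append((r["chrom"], pos + 1, f"snv{vid:06d}", "B_cell_cancer",
                                 f"donor{rng.integers(0, 500):03d}_{d}", "icgc"))
            vid += 1
        for _ in range(int(rng.poisson(m.other_cancer_snv_rate_per_kb * kb))):
            pos = int(rng.integers(r["start"], r["end"]))
            snv_rows.append((r["chrom"], pos + 1, f"snv{vid:06d}", "other_cancer",
                             f"donor{rng.integers(500, 900):03d}_0", "icgc"))
            vid += 1
    with open(out / "snv.tsv", "w") as fh:
        fh.write("chrom\tpos\tvar_id\tvariant_class\tdonor_id\tstudy_id\n")
        for row in sorted(snv_rows):
            fh.write("\t".join(str(x) for x in row) + "\n")

    # TLBPs: B-cell breakpoints concentrated in shore-resident SS components
    shore_ss = [r for r in elements if r["class"] == "SS_component" and r["shore"]]
    other_ss = [r for r in elements if r["class"] == "SS_component" and not r["shore"]]
    se_recs = [r for r in elements if r["class"] == "SE_component"]
    tlbp_rows = []
    for i in range(m.n_bcell_tlbp):
        pool = shore_ss if (shore_ss and rng.random() < m.tlbp_shore_fraction) else other_ss
        r = pool[int(rng.integers(len(pool)))]
        pos = int(rng.integers(r["start"], r["end"]))
        if se_recs and rng.random() < m.tlbp_se_partner_fraction:
            p = se_recs[int(rng.integers(len(se_recs)))]
            p_chrom, p_pos = p["chrom"], int(rng.integers(p["start"], p["end"]))
        else:
            chroms = list(m.chrom_sizes)
            p_chrom = chroms[int(rng.integers(len(chroms)))]
            p_pos = int(rng.integers(100_000, m.chrom_sizes[p_chrom] - 100_000))
        tlbp_rows.append((r["chrom"], pos + 1, f"tl{i:05d}", "B_cell_cancer",
                          f"donor{rng.integers(0, 200):03d}", "icgc",
                          p_chrom, p_pos + 1))
    with open(out / "tlbp.tsv", "w") as fh:
        fh.write("chrom\tpos\tvar_id\tvariant_class\tdonor_id\tstudy_id"
                 "\tpartner_chrom\tpartner_pos\n")
        for row in sorted(tlbp_rows):
            fh.write("\t".join(str(x) for x in row) + "\n")

    # GWAS SNPs: enriched in SS components; replication by trait class
    ss_recs = [r for r in elements if r["class"] == "SS_component"]
    gwas_rows, ld_rows = [], []
    positions = {}
    traits = ("immune", "B_cell_lymphoma", "CLL")
    for i in range(m.n_gwas_snps):
        rsid = f"rs{i:06d}"
        in_ss = rng.random() < 0.4 and ss_recs
        if in_ss:
            r = ss_recs[int(rng.integers(len(ss_recs)))]
            chrom, pos = r["chrom"], int(rng.integers(r["start"], r["end"]))
        else:
            chroms = list(m.chrom_sizes)
            chrom = chroms[int(rng.integers(len(chroms)))]
            pos = int(rng.integers(100_000, m.chrom_sizes[chrom] - 100_000))
        trait = traits[int(rng.integers(len(traits)))]
        rep_frac = (m.gwas_replicated_fraction_ss if in_ss
                    else m.gwas_replicated_fraction_other)
        n_studies = 2 if rng.random() < rep_frac else 1
        for s in range(n_studies):
            gwas_rows.append((chrom, pos + 1, rsid, trait, "", f"study_{trait}_{s}"))
        positions[rsid] = (chrom, pos)
        # an LD block partner near the SNP
        if rng.random() < 0.3:
            partner = f"rs{i:06d}b"
            p_pos = pos + int(rng.integers(1_000, 20_000))
            positions[partner] = (chrom, p_pos)
            ld_rows.append((rsid, partner, round(float(rng.uniform(0.5, 1.0)), 3), "EUR"))
    with open(out / "gwas.tsv", "w") as fh:
        fh.write("chrom\tpos\tvar_id\tvariant_class\tdonor_id\tstudy_id\n")
        for row in sorted(gwas_rows):
            fh.write("\t".join(str(x) for x in row) + "\n")
    with open(out / "ld.tsv", "w") as fh:
        fh.write("rsid_a\trsid_b\tr2\tpopulation\n")
        for row in ld_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    with open(out / "snp_positions.tsv", "w") as fh:
        fh.write("rsid\tchrom\tpos\n")
        for rsid, (chrom, pos) in sorted(positions.items()):
            fh.write(f"{rsid}\t{chrom}\t{pos + 1}\n")


# ---------------------------------------------------------------------------
# contacts


def simulate_contacts(manifest: TruthManifest, outdir) -> None:
    """Generate normal and cancer chromatin-contact sets (BEDPE, binned).

    CGI-classified super-silencer components receive more contacts than
    non-CGI ones by the configured ratio; non-CGI super-silencer flanks are
    contact-depleted (condensation signature); promoters targeted by
    super-silencers receive no enhancer-anchored contacts (shielding
    signature); the cancer set drops a configured fraction of contacts
    anchored at conversion regions.
    """
    m = manifest
    if not m.truth:
        raise GenerationError("epigenome must be generated before contacts")
    out = Path(outdir)
    rng = m.rng("contacts")
    elements = m.truth["elements"]
    B = m.contact_bin

    def bin_of(p):
        return (p // B) * B

    # distal partner anchors avoid element neighborhoods (elements +/- 60 kb),
    # so planted per-element contact counts are not blurred by random hits
    excluded: dict[str, set[int]] = {c: set() for c in m.chrom_sizes}
    element_bins: dict[str, set[int]] = {c: set() for c in m.chrom_sizes}
    for r in elements:
        lo = bin_of(max(0, r["start"] - 60_000))
        hi = bin_of(r["end"] + 60_000)
        excluded[r["chrom"]].update(range(lo, hi + B, B))
        element_bins[r["chrom"]].update(range(bin_of(r["start"]), bin_of(r["end"]) + B, B))

    def random_far_bin(chrom, anchor_start):
        size = m.chrom_sizes[chrom]
        for _ in range(200):
            p = int(rng.integers(100_000, size - 100_000))
            b = bin_of(p)
            if abs(p - anchor_start) >= m.contact_min_span + 2 * B \
                    and b not in excluded[chrom]:
                return b
        raise GenerationError("cannot draw a distal contact bin")

    rows = []

    def add_contact(chrom, a_bin, b_bin, tag):
        a, b = sorted((a_bin, b_bin))
        rows.append((chrom, a, a + B, chrom, b, b + B, tag))

    conv_ss = set(m.truth["conversions_ss"])
    for r in elements:
        mean = m.contacts_per_element
        if r["class"] == "SS_component" and r.get("cgi"):
            mean *= m.cgi_contact_ratio
        a_bin = bin_of((r["start"] + r["end"]) // 2)
        tag = "conv" if r["id"] in conv_ss else "elem"
        for _ in range(int(rng.poisson(mean))):
            add_contact(r["chrom"], a_bin, random_far_bin(r["chrom"], a_bin), tag)
        # flank contacts (condensation signature: depleted around non-CGI SS)
        flank_rate = m.flank_contacts_per_10kb
        if r["class"] == "SS_component" and not r.get("cgi"):
            flank_rate *= m.noncgi_ss_flank_factor
        n_flank = int(rng.poisson(flank_rate * 10.0))  # 100 kb of flank / 10 kb
        placed = 0
        for _ in range(20 * n_flank):
            if placed >= n_flank:
                break
            side = -1 if rng.random() < 0.5 else 1
            off = int(rng.integers(2 * B, 50_000))
            fb = bin_of((r["start"] if side < 0 else r["end"]) + side * off)
            # flank anchors stay off element-occupied bins so per-element
            # contact counts remain exactly the planted ones
            if fb in element_bins[r["chrom"]]:
                continue
            add_contact(r["chrom"], fb, random_far_bin(r["chrom"], fb), tag)
            placed += 1

    # promoter contacts; SS-targeted promoters are shielded from enhancers
    enh_bins = [(r["chrom"], bin_of((r["start"] + r["end"]) // 2))
                for r in elements if r["class"] in ("SE_component", "TE")]
    for g in m.truth["genes"]:
        shielded = g["nearest_class"] == "SS_component"
        p_bin = bin_of(g["tss"])
        for _ in range(int(rng.poisson(m.promoter_contacts_mean))):
            same_chrom_enh = [b for c, b in enh_bins
                              if c == g["chrom"] and abs(b - p_bin) >= m.contact_min_span + 2 * B]
            if (not shielded and same_chrom_enh
                    and rng.random() < m.promoter_enhancer_contact_prob):
                eb = same_chrom_enh[int(rng.integers(len(same_chrom_enh)))]
                add_contact(g["chrom"], p_bin, eb, "prom")
            else:
                add_contact(g["chrom"], p_bin, random_far_bin(g["chrom"], p_bin), "prom")

    with open(out / "contacts.bedpe", "w") as fh:
        for row in sorted(rows):
            fh.write("\t".join(str(x) for x in row[:6]) + "\t.\t1\n")

    # cancer set: conversion-anchored contacts dropped at the high rate
    with open(out / "contacts_cancer.bedpe", "w") as fh:
        for row in sorted(rows):
            drop = (m.conversion_contact_drop if row[6] == "conv"
                    else m.background_contact_drop)
            if rng.random() >= drop:
                fh.write("\t".join(str(x) for x in row[:6]) + "\t.\t1\n")


def simulate_all(manifest: TruthManifest, outdir) -> dict:
    """Generate the full synthetic input set and serialize the truth."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    truth = simulate_epigenome(manifest, out)
    simulate_variants(manifest, out)
    simulate_contacts(manifest, out)
    manifest.to_yaml(out / "manifest.yaml")
    (out / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    return truth
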