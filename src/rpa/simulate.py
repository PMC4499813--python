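"""Synthetic multi-sample short-RNA read datasets with known processing truth.

The generator emulates the phenomena the pipeline is built to detect:

* ``arm_switch`` — two ~22-nt read blocks (the 5' and 3' arms of a pre-miRNA
  hairpin); a subset of cell lines expresses the opposite arm dominantly
  (expression fractions mirrored), the classic arm-switching signature.
* ``arm_loss`` — the minor arm drops below the 10% detection cut-off in a
  subset of lines, so its block disappears there.
* ``coherent_one_block`` / ``coherent_two_block`` — identical expression
  fractions in every line; the one-block variant uses ~17-nt reads and tight
  starts, the short-and-precise regime of TSS-associated RNAs.
* ``noise`` — per-sample random block usage and dispersed starts.
* ``depth_imbalance`` — identical profile shape everywhere but a subset of
  lines sequenced ~5x deeper at the locus: a depth-only negative control
  that must never be called differentially processed.

Replicates are independent multinomial draws from the same per-line
parameters; per-sample depth multipliers emulate variable sequencing depth.
Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import write_reads_bed
from .model import MappedRead

__all__ = ["LocusScenario", "SimulatedDataset", "simulate_locus", "simulate_dataset",
           "benchmark_scenarios"]

SCENARIOS = ("arm_switch", "arm_loss", "coherent_one_block", "coherent_two_block",
             "noise", "depth_imbalance")


@dataclass(frozen=True)
class LocusScenario:
    """Ground-truth description of one simulated locus."""

    scenario: str = "arm_switch"
    n_cell_lines: int = 9
    replicates: int = 2
    switched_lines: tuple[int, ...] = (0, 1, 2)  # line indices affected
    fractions: tuple[float, ...] = (0.8, 0.2)  # per-block expression, main group
    alt_fractions: tuple[float, ...] | None = None  # switched group (default: mirror)
    depth: int = 200
    read_length: int = 22
    length_spread: tuple[float, float, float] = (0.2, 0.6, 0.2)  # P(len-1,len,len+1)
    jitter: int = 1  # read starts uniform over +/- jitter nt
    block_gap: int | None = None  # distance between block starts; default 2*length
    overdispersion: float | None = None  # Dirichlet concentration; None = plain multinomial

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("expression fractions must sum to 1")
        if self.alt_fractions is not None and abs(sum(self.alt_fractions) - 1.0) > 1e-9:
            raise ValueError("alt expression fractions must sum to 1")
        if self.scenario in ("arm_switch", "arm_loss", "depth_imbalance") \
                and not self.switched_lines:
            raise ValueError(f"{self.scenario} needs a non-empty switched subset")

    @property
    def spacing(self) -> int:
        return self.block_gap if self.block_gap is not None else 2 * self.read_length

    def line_fractions(self, line: int) -> tuple[float, ...]:
        switched = line in self.switched_lines
        if self.scenario == "arm_switch":
            return tuple(reversed(self.fractions)) if switched else self.fractions
        if self.scenario == "arm_loss":
            alt = self.alt_fractions or (0.95, 0.05)
            return alt if switched else self.fractions
        if self.scenario == "coherent_one_block":
            return (1.0,)
        return self.fractions

    @property
    def expected_dpl(self) -> bool:
        return self.scenario in ("arm_switch", "arm_loss")

    @property
    def expected_cpl(self) -> bool:
        return self.scenario in ("coherent_one_block", "coherent_two_block")


@dataclass
class SimulatedDataset:
    reads_by_sample: dict[str, list[MappedRead]]
    truth: pd.DataFrame
    replicate_map: dict[str, str]  # sample -> cell line
    samples: list[str]
    genome_size: int
    chrom: str


def _sample_names(n_lines: int, replicates: int) -> tuple[list[str], dict[str, str]]:
    samples, rep_map = [], {}
    for i in range(n_lines):
        line = f"L{i + 1}"
        for r in range(replicates):
            s = f"{line}.r{r + 1}"
            samples.append(s)
            rep_map[s] = line
    return samples, rep_map


def simulate_locus(
    scenario: LocusScenario,
    rng: np.random.Generator,
    chrom: str = "chrS",
    origin: int = 1000,
    strand: str = "+",
    depth_multipliers: dict[str, float] | None = None,
) -> tuple[dict[str, list[MappedRead]], dict]:
    """Draw reads for every sample at one locus; returns reads plus the truth
    record.

    Per sample, block read counts are multinomial in the line's expression
    fractions; read starts are jittered uniformly over ``+/- jitter`` nt
    (spread controls entropy) and lengths vary by +/- 1 nt around the mode.
    Identical reads are collapsed with a multiplicity count.
    """
    samples, rep_map = _sample_names(scenario.n_cell_lines, scenario.replicates)
    mult = depth_multipliers or {s: 1.0 for s in samples}
    n_blocks = len(scenario.line_fractions(0))
    block_starts = [origin + b * scenario.spacing for b in range(n_blocks)]
    len_deltas = np.array([-1, 0, 1])

    eff_jitter = scenario.jitter * (3 if scenario.scenario == "noise" else 1)
    reads_out: dict[str, list[MappedRead]] = {}
    for s in samples:
        line_idx = int(rep_map[s][1:]) - 1
        fr = np.asarray(scenario.line_fractions(line_idx))
        depth = scenario.depth * mult.get(s, 1.0)
        if scenario.scenario == "depth_imbalance" and line_idx in scenario.switched_lines:
            depth *= 5.0
        depth = max(1, int(round(depth)))
        if scenario.scenario == "noise":
            fr = rng.dirichlet(np.ones(len(fr)) * 2.0)
        elif scenario.overdispersion is not None and len(fr) > 1:
            # Dirichlet-multinomial replicate noise beyond pure sampling
            fr = rng.dirichlet(np.maximum(fr, 1e-9) * scenario.overdispersion)
        counts = rng.multinomial(depth, fr)
        jitter = eff_jitter
        collapsed: dict[tuple[int, int], int] = {}
        for b, nb in enumerate(counts):
            if nb == 0:
                continue
            if jitter > 0:
                offsets = rng.integers(-jitter, jitter + 1, size=nb)
            else:
                offsets = np.zeros(nb, dtype=int)
            lengths = scenario.read_length + rng.choice(
                len_deltas, size=nb, p=scenario.length_spread
            )
            for off, ln in zip(offsets, lengths):
                key = (block_starts[b] + int(off), int(ln))
                collapsed[key] = collapsed.get(key, 0) + 1
        reads_out[s] = [
            MappedRead(chrom, st, st + ln, strand, cnt, s)
            for (st, ln), cnt in sorted(collapsed.items())
        ]

    span_end = block_starts[-1] + scenario.read_length + eff_jitter + 2
    truth = {
        "chrom": chrom,
        "start": origin - eff_jitter - 1,
        "end": span_end,
        "strand": strand,
        "scenario": scenario.scenario,
        "expected_dpl": scenario.expected_dpl,
        "expected_cpl": scenario.expected_cpl,
        "switched_lines": ",".join(f"L{i + 1}" for i in scenario.switched_lines),
    }
    return reads_out, truth


def simulate_dataset(
    scenarios: list[LocusScenario],
    seed: int = 0,
    out_dir: str | Path | None = None,
    chrom: str = "chrS",
    spacing: int = 2000,
    depth_range: tuple[float, float] = (1.0, 5.0),
) -> SimulatedDataset:
    """Simulate a whole dataset: one locus per scenario, laid out every
    ``spacing`` nt on one synthetic chromosome.

    Per-sample depth multipliers (variable sequencing depth) are drawn once
    for the dataset from ``depth_range`` and apply at every locus.  When
    ``out_dir`` is given, per-sample BED files, a truth table TSV and toy
    annotation BEDs (a miRNA annotation over every arm-switch locus, a TSS
    upstream of every coherent one-block locus) are written.
    """
    if not scenarios:
        empty = SimulatedDataset({}, pd.DataFrame(), {}, [], spacing, chrom)
        if out_dir is not None:
            Path(out_dir).mkdir(parents=True, exist_ok=True)
            empty.truth.to_csv(Path(out_dir) / "truth.tsv", sep="\t", index=False)
        return empty

    layouts = {(sc.n_cell_lines, sc.replicates) for sc in scenarios}
    if len(layouts) > 1:
        raise ValueError("all scenarios must share the same sample layout")
    samples, rep_map = _sample_names(*next(iter(layouts)))

    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(len(scenarios) + 1)
    rng0 = np.random.default_rng(child_seeds[0])
    lo, hi = depth_range
    multipliers = {s: float(rng0.uniform(lo, hi)) for s in samples}

    max_span = max(
        len(sc.line_fractions(0)) * sc.spacing + sc.read_length + 50 for sc in scenarios
    )
    if spacing <= max_span:
        raise ValueError("locus spacing too small: placements would overlap")

    reads_by_sample: dict[str, list[MappedRead]] = {s: [] for s in samples}
    truth_rows = []
    for i, sc in enumerate(scenarios):
        origin = 1000 + i * spacing
        rng = np.random.default_rng(child_seeds[i + 1])
        reads, truth = simulate_locus(
            sc, rng, chrom=chrom, origin=origin, depth_multipliers=multipliers
        )
        truth["locus_id"] = i + 1
        truth_rows.append(truth)
        for s in samples:
            reads_by_sample[s].extend(reads[s])

    truth_df = pd.DataFrame(truth_rows)
    genome_size = 1000 + spacing * len(scenarios) + 1000
    ds = SimulatedDataset(
        reads_by_sample=reads_by_sample,
        truth=truth_df,
        replicate_map=rep_map,
        samples=samples,
        genome_size=genome_size,
        chrom=chrom,
    )
    if out_dir is not None:
        _write_dataset(ds, truth_df, scenarios, Path(out_dir))
    return ds


def _write_dataset(
    ds: SimulatedDataset,
    truth: pd.DataFrame,
    scenarios: list[LocusScenario],
    out: Path,
) -> None:
    out.mkdir(parents=True, exist_ok=True)
    for s in ds.samples:
        write_reads_bed(ds.reads_by_sample[s], out / f"{s}.bed")
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    with open(out / "annotations.ncrna.bed", "w") as nc, \
            open(out / "annotations.tss.bed", "w") as tssf:
        for row, sc in zip(truth.itertuples(), scenarios):
            if sc.scenario in ("arm_switch", "arm_loss"):
                nc.write(f"{row.chrom}\t{row.start}\t{row.end}\tmiRNA\t0\t{row.strand}\n")
            if sc.scenario == "coherent_one_block":
                pos = row.start - 100
                tssf.write(f"{row.chrom}\t{pos}\t{pos + 1}\tTSS\t0\t{row.strand}\n")
    with open(out / "samples.tsv", "w") as sf:
        sf.write("sample\tcell_line\treads\n")
        for s in ds.samples:
            sf.write(f"{s}\t{ds.replicate_map[s]}\t{s}.bed\n")


def benchmark_scenarios(
    n_arm_switch: int = 20,
    n_coherent: int = 20,
    n_noise: int = 10,
    n_depth_controls: int = 5,
    dominant_fraction: float = 0.8,
    n_switched: int = 3,
    depth: int = 200,
) -> list[LocusScenario]:
    """The bundled benchmark layout: 9 cell lines x 2 replicates, arm-switch
    loci with the dominant arm at 0.8 and 3 switched lines, coherent loci
    split between the one-block (~17 nt, short/precise) and two-block kinds,
    noise loci, and depth-only negative controls."""
    base = LocusScenario(
        fractions=(dominant_fraction, round(1 - dominant_fraction, 10)),
        switched_lines=tuple(range(n_switched)),
        depth=depth,
    )
    scs: list[LocusScenario] = []
    scs += [replace(base, scenario="arm_switch") for _ in range(n_arm_switch)]
    half = n_coherent // 2
    scs += [
        replace(base, scenario="coherent_one_block", read_length=17, jitter=1)
        for _ in range(half)
    ]
    scs += [replace(base, scenario="coherent_two_block") for _ in range(n_coherent - half)]
    scs += [replace(base, scenario="noise", fractions=(0.5, 0.3, 0.2))
            for _ in range(n_noise)]
    scs += [replace(base, scenario="depth_imbalance") for _ in range(n_depth_controls)]
    return scs
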