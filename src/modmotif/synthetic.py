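"""Synthetic genomes, modification tracks and peak sets with planted motifs.

The generator emulates the statistical shape of the real inputs: an
assembly with a chosen GC fraction, per-CpG modification levels with the
bounded, skewed shape of maximum-likelihood bisulfite estimates (Beta
distributed), and ChIP-seq-like peak regions whose summits carry planted
motif occurrences with Gaussian positional jitter. Planted instances can
carry any of the six CpG modification patterns; every plant is recorded in
a truth table so downstream recovery can be checked against ground truth.

Background CpGs (outside modified plants) receive low-level modification
draws (default Beta(1, 20)) so that modified symbols occur at realistic,
nonzero background frequencies — without this the modified-background
pseudocount equations would be degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Tuple, Union

import numpy as np
import pandas as pd

from .genome import ModificationRecord, Peak, write_fasta, write_track
from .hypotheses import CPG_PATTERNS
from .motifs import _IUPAC  # standard IUPAC expansions for plant sampling

CHROM_NAME = "chrSim"

#: Which level field each modified-symbol target fills.
_LEVEL_FIELD = {"m": "level_m", "h": "level_h"}


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror the analysis protocol: 500 bp peak regions, a
    single-CpG E-box motif, complete-methylation plants with levels from
    Beta(8, 2) (mostly high, as real CpG methylation is), and low-level
    Beta(1, 20) background modification.
    """

    genome_length: int = 300_000
    gc_fraction: float = 0.42
    n_peaks: int = 500
    peak_width: int = 500
    motif: str = "CACGTG"
    plant_fraction: float = 1.0
    plant_modified_fraction: float = 1.0
    pattern: str = "m1"
    modification_level_beta: Tuple[float, float] = (8.0, 2.0)
    background_level_beta: Tuple[float, float] = (1.0, 20.0)
    positional_jitter_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gc_fraction", "plant_fraction", "plant_modified_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name} must lie in [0, 1], got {v!r}")
        if self.n_peaks < 1 or self.genome_length < 1:
            raise SimulationError("need at least one peak and a positive genome length")
        if self.peak_width > self.genome_length // self.n_peaks:
            raise SimulationError(
                f"infeasible packing: peak_width {self.peak_width} exceeds "
                f"genome_length / n_peaks = {self.genome_length // self.n_peaks}")
        if self.pattern not in CPG_PATTERNS:
            raise SimulationError(f"unknown CpG pattern {self.pattern!r}")
        if self.peak_width < len(self.motif):
            raise SimulationError("peaks must be wider than the motif")


@dataclass
class SimResult:
    genome: Dict[str, str]
    records: List[ModificationRecord]
    peaks: List[Peak]
    truth: pd.DataFrame


def _sample_instance(motif: str, rng: np.random.Generator) -> str:
    """Concrete A/C/G/T instance of an IUPAC motif string."""
    out = []
    for ch in motif:
        up = ch.upper()
        if up in "ACGT":
            out.append(up)
        elif up in _IUPAC:
            out.append(rng.choice(list(_IUPAC[up])))
        else:
            raise SimulationError(f"motif character {ch!r} is not plain IUPAC")
    return "".join(out)


def simulate(config: SimConfig) -> SimResult:
    """Generate (genome, modification records, peaks, truth table).

    Fully deterministic given ``config.seed``. Peaks are laid on a regular
    grid of cells (one per peak) with a random in-cell offset, so they can
    never overlap. Planted motifs are centred on peak summits plus
    Gaussian jitter; modified plants receive pattern-specific Beta levels
    at the motif's CpGs, one record per modified strand.
    """
    rng = np.random.default_rng(config.seed)
    gc = config.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    chars = np.array(list("ACGT"))
    seq = rng.choice(chars, size=config.genome_length, p=probs)

    spacing = config.genome_length // config.n_peaks
    plus_target, minus_target = CPG_PATTERNS[config.pattern]
    a_mod, b_mod = config.modification_level_beta

    peaks: List[Peak] = []
    truth_rows = []
    modified_cpg_levels: Dict[Tuple[int, str], Tuple[str, float]] = {}
    planted_spans: List[Tuple[int, int]] = []

    for i in range(config.n_peaks):
        cell_start = i * spacing
        start = cell_start + int(rng.integers(0, spacing - config.peak_width + 1))
        end = start + config.peak_width
        summit = start + config.peak_width // 2
        peaks.append(Peak(chrom=CHROM_NAME, start=start, end=end, summit=summit))

        planted = rng.random() < config.plant_fraction
        modified = planted and rng.random() < config.plant_modified_fraction
        plant_start = -1
        if planted:
            instance = _sample_instance(config.motif, rng)
            jitter = int(round(rng.normal(0.0, config.positional_jitter_sd)))
            plant_start = summit - len(instance) // 2 + jitter
            plant_start = max(start, min(end - len(instance), plant_start))
            seq[plant_start:plant_start + len(instance)] = list(instance)
            planted_spans.append((plant_start, plant_start + len(instance)))
            if modified:
                for j in range(len(instance) - 1):
                    if instance[j] == "C" and instance[j + 1] == "G":
                        if plus_target is not None:
                            lvl = float(rng.beta(a_mod, b_mod))
                            modified_cpg_levels[(plant_start + j, "+")] = (
                                plus_target, lvl)
                        if minus_target is not None:
                            lvl = float(rng.beta(a_mod, b_mod))
                            modified_cpg_levels[(plant_start + j + 1, "-")] = (
                                {"1": "m", "2": "h"}[minus_target], lvl)
        truth_rows.append({"peak": i, "chrom": CHROM_NAME, "start": start,
                           "end": end, "summit": summit, "planted": planted,
                           "modified": modified, "plant_start": plant_start,
                           "pattern": config.pattern if modified else ""})

    genome_str = "".join(seq)
    a_bg, b_bg = config.background_level_beta
    records: List[ModificationRecord] = []
    for pos in range(config.genome_length - 1):
        if genome_str[pos] == "C" and genome_str[pos + 1] == "G":
            for pos_s, strand in ((pos, "+"), (pos + 1, "-")):
                target_lvl = modified_cpg_levels.get((pos_s, strand))
                if target_lvl is not None:
                    target, lvl = target_lvl
                    lm = lvl if target == "m" else 0.0
                    lh = lvl if target == "h" else 0.0
                else:
                    lm, lh = float(rng.beta(a_bg, b_bg)), 0.0
                records.append(ModificationRecord(
                    chrom=CHROM_NAME, pos=pos_s, strand=strand,
                    level_m=lm, level_h=lh, conflicts=0))

    truth = pd.DataFrame(truth_rows)
    return SimResult(genome={CHROM_NAME: genome_str}, records=records,
                     peaks=peaks, truth=truth)


def write_simulation(result: SimResult, out_dir: Union[str, Path]) -> Dict[str, Path]:
    """Write FASTA, modification track TSV, narrowPeak BED and truth TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "genome.fa",
        "tracks": out / "modifications.tsv",
        "peaks": out / "peaks.narrowPeak",
        "truth": out / "truth.tsv",
    }
    write_fasta(result.genome, paths["fasta"])
    write_track(result.records, paths["tracks"])
    with open(paths["peaks"], "w") as fh:
        for i, pk in enumerate(result.peaks):
            fh.write(f"{pk.chrom}\t{pk.start}\t{pk.end}\tpeak{i}\t0\t.\t0\t-1\t-1\t"
                     f"{pk.summit - pk.start}\n")
    result.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
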