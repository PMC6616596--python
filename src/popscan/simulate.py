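"""Forward-in-time Wright-Fisher simulator of multi-population SNP panels.

Discrete, non-overlapping generations of diploid individuals. Each
offspring draws two parents uniformly with replacement from its
population in the previous generation; each transmitted gamete is built
by recombining the parent's two haplotypes, with crossovers placed as a
Poisson process along the chromosome at a constant per-bp rate.
Founder haplotypes are at linkage equilibrium with per-SNP allele
frequencies drawn uniformly on [0.05, 0.95], mimicking the
common-variant ascertainment of SNP arrays. No new mutation occurs
during the simulated epoch, so all variation descends from the founder
generation and drift/recombination fully determine the outcome.

Population splits copy a parent deme's gene pool at a stated number of
generations before sampling; an admixture event redirects a fraction of
one deme's parent draws to a donor deme for a single generation.
Genotype missingness is applied i.i.d. at a configurable rate. With a
fixed seed the output is fully deterministic.

Forward simulation (rather than a coalescent) keeps arbitrary
population-size trajectories and admixture timing exact by
construction, which is what the Ne-recovery tests need.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .panel import MISSING, GenotypePanel
from . import io_plink


class SimulationError(ValueError):
    pass


@dataclass
class PopulationConfig:
    """One deme: label and diploid size per generation, most recent last.

    A population present from the start of the simulation lists one size
    per simulated generation; a population created by a split lists
    sizes only for the generations it exists (its first listed size is
    its size in the generation of the split event).
    """

    label: str
    size_per_generation: list[int]

    def __post_init__(self) -> None:
        if any(s < 2 for s in self.size_per_generation):
            raise SimulationError(
                f"population {self.label}: sizes must be >= 2")


@dataclass
class SplitEvent:
    generation: int  # generations before sampling at which the child appears
    parent: str
    child: str


@dataclass
class AdmixtureEvent:
    generation: int
    recipient: str
    donor: str
    fraction: float

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction < 1.0:
            raise SimulationError("admixture fraction must be in (0, 1)")


@dataclass
class DemographyConfig:
    populations: list[PopulationConfig]
    split_events: list[SplitEvent] = field(default_factory=list)
    admixture_events: list[AdmixtureEvent] = field(default_factory=list)
    sample_sizes: dict[str, int] = field(default_factory=dict)

    @property
    def n_generations(self) -> int:
        return max(len(p.size_per_generation) for p in self.populations)

    def validate(self) -> None:
        labels = {p.label for p in self.populations}
        if len(labels) != len(self.populations):
            raise SimulationError("duplicate population labels")
        by_label = {p.label: p for p in self.populations}
        g = self.n_generations
        for ev in self.split_events:
            if ev.parent not in labels or ev.child not in labels:
                raise SimulationError(f"split references unknown population "
                                      f"({ev.parent} -> {ev.child})")
            child_span = len(by_label[ev.child].size_per_generation)
            if child_span != ev.generation:
                raise SimulationError(
                    f"split child {ev.child}: lists {child_span} sizes but "
                    f"splits {ev.generation} generations before sampling")
        for ev in self.admixture_events:
            if ev.recipient not in labels or ev.donor not in labels:
                raise SimulationError("admixture references unknown "
                                      "population")
            if not 0 < ev.generation <= g:
                raise SimulationError("admixture generation out of range")
        for label, n in self.sample_sizes.items():
            if label not in labels:
                raise SimulationError(f"sample_sizes references unknown "
                                      f"population {label!r}")
            if n > by_label[label].size_per_generation[-1]:
                raise SimulationError(
                    f"cannot sample {n} diploids from {label} of final size "
                    f"{by_label[label].size_per_generation[-1]}")


@dataclass
class GenomeConfig:
    n_chromosomes: int = 1
    chromosome_length_bp: int = 50_000_000
    n_snps: int = 5_000
    recombination_rate: float = 1e-8  # per bp per generation
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.recombination_rate < 0:
            raise SimulationError("recombination_rate must be >= 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise SimulationError("missing_rate must be in [0, 1)")
        if self.n_snps > self.n_chromosomes * self.chromosome_length_bp:
            raise SimulationError("more SNPs than base pairs")


def constant_demography(label: str, size: int, n_generations: int,
                        n_sampled: int) -> DemographyConfig:
    """Single closed population of constant size — the simplest scenario."""
    return DemographyConfig(
        populations=[PopulationConfig(label, [size] * n_generations)],
        sample_sizes={label: n_sampled},
    )


def _founder_haplotypes(rng: np.random.Generator, n_haplotypes: int,
                        freqs: np.ndarray) -> np.ndarray:
    return (rng.random((n_haplotypes, freqs.size)) < freqs).astype(np.uint8)


def _make_gamete(rng: np.random.Generator, h0: np.ndarray, h1: np.ndarray,
                 pos: np.ndarray, length_bp: int, rate: float) -> np.ndarray:
    """Recombine one parent's haplotype pair into a transmitted gamete."""
    start = rng.integers(0, 2)
    if rate == 0.0:
        return (h0 if start == 0 else h1).copy()
    n_x = rng.poisson(rate * length_bp)
    if n_x == 0:
        return (h0 if start == 0 else h1).copy()
    breaks = np.sort(rng.integers(1, length_bp + 1, size=n_x))
    which = (start + np.searchsorted(breaks, pos, side="left")) % 2
    return np.where(which == 0, h0, h1)


class _Deme:
    """Haplotypes of one population at the current generation."""

    def __init__(self, haplotypes: np.ndarray):
        self.h = haplotypes  # (2N, n_snps) uint8

    @property
    def n_diploid(self) -> int:
        return self.h.shape[0] // 2


def simulate(demography: DemographyConfig,
             genome: GenomeConfig) -> GenotypePanel:
    """Run the Wright-Fisher process and return the sampled panel.

    Generations are simulated from ``demography.n_generations`` before
    sampling down to generation 0; sampling takes the first
    ``sample_sizes[label]`` diploids of each deme (individuals are
    exchangeable). Raises :class:`SimulationError` if a deme's size ever
    falls below 2 (extinction) before its sampling time.
    """
    demography.validate()
    rng = np.random.default_rng(genome.seed)

    # SNP positions: distinct uniform draws per chromosome, sorted
    per_chrom = np.full(genome.n_chromosomes,
                        genome.n_snps // genome.n_chromosomes)
    per_chrom[: genome.n_snps % genome.n_chromosomes] += 1
    chrom_pos: list[np.ndarray] = []
    for c in range(genome.n_chromosomes):
        want = int(per_chrom[c])
        pos = np.unique(rng.integers(
            1, genome.chromosome_length_bp + 1, size=want))
        while pos.size < want:  # top up after collisions
            extra = rng.integers(1, genome.chromosome_length_bp + 1,
                                 size=want - pos.size)
            pos = np.unique(np.concatenate([pos, extra]))
        chrom_pos.append(pos.astype(np.int64))
    n_snps = int(sum(p.size for p in chrom_pos))
    snp_chrom = np.concatenate([
        np.full(p.size, c + 1) for c, p in enumerate(chrom_pos)])
    snp_lo = np.cumsum([0] + [p.size for p in chrom_pos])

    freqs = rng.uniform(0.05, 0.95, size=n_snps)

    by_label = {p.label: p for p in demography.populations}
    g_total = demography.n_generations
    # start_gen[label]: generations-before-sampling at which the deme exists
    start_gen = {p.label: len(p.size_per_generation)
                 for p in demography.populations}
    split_child = {ev.child: ev for ev in demography.split_events}
    admix_at: dict[tuple[str, int], AdmixtureEvent] = {
        (ev.recipient, ev.generation): ev
        for ev in demography.admixture_events}

    demes: dict[str, _Deme] = {}
    for p in demography.populations:
        if start_gen[p.label] == g_total and p.label not in split_child:
            demes[p.label] = _Deme(_founder_haplotypes(
                rng, 2 * p.size_per_generation[0], freqs))

    def reproduce(target_label: str, size: int, gen_now: int) -> np.ndarray:
        """Build 2*size gametes for deme `target_label` at `gen_now`."""
        source = demes[target_label]
        ev = admix_at.get((target_label, gen_now))
        out = np.empty((2 * size, n_snps), dtype=np.uint8)
        for i in range(size):
            for slot in range(2):
                pool = source
                if ev is not None and rng.random() < ev.fraction:
                    pool = demes[ev.donor]
                parent = int(rng.integers(0, pool.n_diploid))
                gam = np.empty(n_snps, dtype=np.uint8)
                for c in range(genome.n_chromosomes):
                    lo, hi = snp_lo[c], snp_lo[c + 1]
                    gam[lo:hi] = _make_gamete(
                        rng,
                        pool.h[2 * parent, lo:hi],
                        pool.h[2 * parent + 1, lo:hi],
                        chrom_pos[c], genome.chromosome_length_bp,
                        genome.recombination_rate)
                out[2 * i + slot] = gam
        return out

    # iterate generations-before-sampling: g_total-1 down to 0
    for gen in range(g_total - 1, -1, -1):
        new_demes: dict[str, _Deme] = {}
        for p in demography.populations:
            if start_gen[p.label] <= gen:
                continue  # not yet born
            idx = len(p.size_per_generation) - 1 - gen
            size = p.size_per_generation[idx]
            if p.label in demes:
                new_demes[p.label] = _Deme(
                    reproduce(p.label, size, gen + 1))
            else:
                # birth by split: offspring drawn from the parent deme
                ev = split_child[p.label]
                if ev.parent not in demes:
                    raise SimulationError(
                        f"split parent {ev.parent} does not exist at "
                        f"generation {gen}")
                demes[p.label] = demes[ev.parent]
                new_demes[p.label] = _Deme(
                    reproduce(p.label, size, gen + 1))
                del demes[p.label]
        demes.update(new_demes)

    # sample and assemble the panel
    sample_sizes = demography.sample_sizes or {
        p.label: p.size_per_generation[-1] for p in demography.populations}
    rows, iids, pops = [], [], []
    for label in sorted(sample_sizes):
        if label not in demes:
            raise SimulationError(f"population {label} never simulated")
        n = sample_sizes[label]
        h = demes[label].h
        geno = h[0:2 * n:2] + h[1:2 * n:2]
        rows.append(geno.astype(np.int8))
        iids.extend(f"{label}_{i + 1}" for i in range(n))
        pops.extend([label] * n)
    dosage = np.concatenate(rows, axis=0)

    if genome.missing_rate > 0:
        mask = rng.random(dosage.shape) < genome.missing_rate
        dosage = np.where(mask, np.int8(MISSING), dosage)

    markers = pd.DataFrame({
        "id": [f"snp{c}_{p}" for c, p in zip(snp_chrom,
                                             np.concatenate(chrom_pos))],
        "chromosome": snp_chrom.astype(str),
        "position": np.concatenate(chrom_pos),
        "allele_a": "A",
        "allele_b": "B",
    })
    samples = pd.DataFrame({
        "individual_id": iids,
        "population": pops,
        "sex": "unknown",
    })
    return GenotypePanel(markers, samples, dosage)


def write_fixture(panel: GenotypePanel, out_prefix: str | Path,
                  demography: DemographyConfig | None = None,
                  genome: GenomeConfig | None = None) -> None:
    """Write PLINK text+binary file sets plus a YAML truth file.

    The truth file records the generating demography (per-generation
    sizes, events, seed) so recovery tests can compare estimates with
    the known history.
    """
    prefix = Path(out_prefix)
    io_plink.write_panel(panel, prefix, format="ped")
    io_plink.write_panel(panel, prefix, format="bed")
    truth: dict = {}
    if demography is not None:
        truth["populations"] = [
            {"label": p.label, "size_per_generation": list(p.size_per_generation)}
            for p in demography.populations]
        truth["split_events"] = [
            {"generation": e.generation, "parent": e.parent, "child": e.child}
            for e in demography.split_events]
        truth["admixture_events"] = [
            {"generation": e.generation, "recipient": e.recipient,
             "donor": e.donor, "fraction": e.fraction}
            for e in demography.admixture_events]
        truth["sample_sizes"] = dict(demography.sample_sizes)
    if genome is not None:
        truth["genome"] = {
            "n_chromosomes": genome.n_chromosomes,
            "chromosome_length_bp": genome.chromosome_length_bp,
            "n_snps": genome.n_snps,
            "recombination_rate": genome.recombination_rate,
            "missing_rate": genome.missing_rate,
            "seed": genome.seed,
        }
    with open(prefix.with_suffix(".truth.yaml"), "w") as fh:
        yaml.safe_dump(truth, fh, sort_keys=True)
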