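"""Haplotype-based case-control genotype simulation.

Multilocus SNP genotypes are generated by drawing ordered haplotype pairs
from a panel of phased haplotypes with known frequencies ``f_H``.  Control
pairs follow the inbreeding-augmented law

    phi(H, H') = (1 - Fst) f_H f_H' + delta(H, H') Fst f_H,

which reduces to Hardy-Weinberg equilibrium (two independent draws) at
``Fst = 0`` and inflates homozygosity for ``Fst > 0``.  Case pairs reweight
the same law by genotype odds ratios at a designated causal locus:

    phi_case(H, H')  ∝  r_het^[het at causal]  r_hom^[minor hom]  phi(H, H').

Phase is discarded; each locus is reported as a minor-allele count (0/1/2),
with the minor allele defined from the panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .dataset import GenotypeDataset

__all__ = [
    "HaplotypePanel",
    "PairingModel",
    "DiseaseModel",
    "load_panel",
    "load_panel_file",
    "nat2_panel",
    "pair_probabilities",
    "sample_haplotype_pair",
    "case_pair_weights",
    "simulate_dataset",
]


class PanelFormatError(ValueError):
    """Raised when a haplotype table violates the panel format."""


@dataclass(frozen=True)
class PairingModel:
    """Haplotype-pair law parameterized by the fixation index ``f_st``.

    ``f_st = 0`` gives independent haplotype draws (HWE); ``f_st = 1``
    duplicates a single draw (fully inbred).
    """

    f_st: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_st <= 1.0:
            raise ValueError(f"f_st must lie in [0, 1], got {self.f_st}")


@dataclass(frozen=True)
class DiseaseModel:
    """Genotype odds ratios at a causal locus.

    ``r_het`` and ``r_hom`` are the odds ratios of the heterozygote and the
    minor-allele homozygote relative to the major homozygote.  The
    constructors encode the usual genetic modes for a per-mode odds ratio
    ``theta``: additive ``(theta, theta**2)``, dominant ``(theta, theta)``,
    recessive ``(1, theta)``.
    """

    causal_index: int
    r_het: float = 1.0
    r_hom: float = 1.0
    mode: str = "custom"

    def __post_init__(self) -> None:
        if self.causal_index < 0:
            raise ValueError("causal_index must be non-negative")
        if self.r_het < 0 or self.r_hom < 0:
            raise ValueError("odds ratios must be non-negative")

    @classmethod
    def additive(cls, causal_index: int, theta: float) -> "DiseaseModel":
        return cls(causal_index, theta, theta**2, mode="additive")

    @classmethod
    def dominant(cls, causal_index: int, theta: float) -> "DiseaseModel":
        return cls(causal_index, theta, theta, mode="dominant")

    @classmethod
    def recessive(cls, causal_index: int, theta: float) -> "DiseaseModel":
        return cls(causal_index, 1.0, theta, mode="recessive")

    @classmethod
    def null(cls, causal_index: int = 0) -> "DiseaseModel":
        return cls(causal_index, 1.0, 1.0, mode="null")

    @property
    def is_null(self) -> bool:
        return self.r_het == 1.0 and self.r_hom == 1.0


@dataclass
class HaplotypePanel:
    """A diallelic haplotype panel: strings over allele symbols + frequencies.

    Frequencies are renormalized to sum to one at construction; the raw
    values remain available as :attr:`raw_frequencies`.  Each locus carries
    at most two allele symbols; the minor allele is the symbol whose panel
    frequency is <= 0.5 (lexicographically smaller symbol on a tie).
    Monomorphic loci are flagged and always yield genotype 0.
    """

    haplotypes: tuple[str, ...]
    frequencies: np.ndarray
    raw_frequencies: np.ndarray = field(repr=False)

    # derived
    q: int = field(init=False)
    n_hap: int = field(init=False)
    minor_allele: list = field(init=False, repr=False)
    maf_panel: np.ndarray = field(init=False, repr=False)
    monomorphic: np.ndarray = field(init=False, repr=False)
    _minor_dosage: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.haplotypes) < 2:
            raise PanelFormatError("a panel needs at least two haplotypes")
        lengths = {len(h) for h in self.haplotypes}
        if len(lengths) != 1:
            raise PanelFormatError(f"haplotype strings of unequal length: {sorted(lengths)}")
        self.q = lengths.pop()
        self.n_hap = len(self.haplotypes)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.frequencies.shape != (self.n_hap,):
            raise PanelFormatError("one frequency per haplotype is required")
        if np.any(self.frequencies <= 0):
            raise ValueError("haplotype frequencies must be strictly positive")
        total = self.frequencies.sum()
        self.frequencies = self.frequencies / total

        chars = np.array([list(h) for h in self.haplotypes])  # (n_hap, q)
        self.minor_allele = []
        maf = np.zeros(self.q)
        mono = np.zeros(self.q, dtype=bool)
        dosage = np.zeros((self.n_hap, self.q), dtype=np.int8)
        for k in range(self.q):
            alleles = sorted(set(chars[:, k]))
            if len(alleles) > 2:
                raise PanelFormatError(
                    f"locus {k + 1} carries {len(alleles)} alleles; panel must be diallelic"
                )
            if len(alleles) == 1:
                mono[k] = True
                self.minor_allele.append(None)
                continue
            freqs = {a: self.frequencies[chars[:, k] == a].sum() for a in alleles}
            # symbol with frequency <= 0.5; lexicographically smaller on a tie
            a0, a1 = alleles
            minor = a0 if freqs[a0] <= freqs[a1] else a1
            self.minor_allele.append(minor)
            maf[k] = freqs[minor]
            dosage[:, k] = (chars[:, k] == minor).astype(np.int8)
        self.maf_panel = maf
        self.monomorphic = mono
        self._minor_dosage = dosage

    def genotypes_from_pairs(self, i: np.ndarray, j: np.ndarray) -> np.ndarray:
        """Minor-allele counts (0/1/2) for ordered haplotype-index pairs."""
        return self._minor_dosage[np.asarray(i)] + self._minor_dosage[np.asarray(j)]


def load_panel(rows: Iterable[tuple[str, float]]) -> HaplotypePanel:
    """Build a :class:`HaplotypePanel` from (haplotype-string, frequency) rows."""
    haps, freqs = [], []
    for hap, freq in rows:
        haps.append(str(hap).strip())
        freqs.append(float(freq))
    raw = np.asarray(freqs, dtype=float)
    return HaplotypePanel(tuple(haps), raw.copy(), raw)


def load_panel_file(path: str | Path) -> HaplotypePanel:
    """Read a two-column (haplotype, frequency) whitespace/TSV panel file."""
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise PanelFormatError(f"expected two columns, got {len(parts)}: {line!r}")
        rows.append((parts[0], float(parts[1])))
    return load_panel(rows)


def nat2_panel() -> HaplotypePanel:
    """The packaged 18-locus NAT2 haplotype panel (16 CEU haplotypes)."""
    ref = resources.files("pchiassoc").joinpath("data/nat2_haplotypes.tsv")
    with resources.as_file(ref) as path:
        return load_panel_file(path)


def pair_probabilities(panel: HaplotypePanel, pairing: PairingModel) -> np.ndarray:
    """Ordered-pair law phi(H, H') as an (n_hap, n_hap) matrix summing to 1."""
    f = panel.frequencies
    phi = (1.0 - pairing.f_st) * np.outer(f, f)
    phi[np.diag_indices_from(phi)] += pairing.f_st * f
    return phi


def _sample_pair_indices(
    panel: HaplotypePanel, f_st: float, size: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized mixture sampler for the ordered-pair law.

    With probability ``f_st`` the two haplotypes are a duplicated single
    draw, otherwise two independent draws — an exact representation of
    phi(H, H') for ordered pairs.
    """
    f = panel.frequencies
    i = rng.choice(panel.n_hap, size=size, p=f)
    j = rng.choice(panel.n_hap, size=size, p=f)
    if f_st > 0:
        dup = rng.random(size) < f_st
        j[dup] = i[dup]
    return i, j


def sample_haplotype_pair(
    panel: HaplotypePanel, pairing: PairingModel, rng: np.random.Generator
) -> tuple[str, str]:
    """Draw one ordered haplotype pair from the pairing law."""
    i, j = _sample_pair_indices(panel, pairing.f_st, 1, rng)
    return panel.haplotypes[int(i[0])], panel.haplotypes[int(j[0])]


def case_pair_weights(
    panel: HaplotypePanel, pairing: PairingModel, disease: DiseaseModel
) -> np.ndarray:
    """Case distribution over ordered haplotype pairs.

    Each pair's base probability phi(H, H') is multiplied by ``r_het`` if the
    pair is heterozygous at the causal locus and by ``r_hom`` if it is
    minor-allele homozygous, then the matrix is renormalized to sum to 1.
    """
    c = disease.causal_index
    if not 0 <= c < panel.q:
        raise ValueError(f"causal index {c} outside panel of {panel.q} loci")
    if panel.monomorphic[c]:
        raise ValueError(f"causal locus {c + 1} is monomorphic in the panel")
    phi = pair_probabilities(panel, pairing)
    if disease.is_null:
        return phi  # null odds ratios: the case law is the control law, exactly
    dose = panel._minor_dosage[:, c]
    g = dose[:, None] + dose[None, :]  # genotype at causal locus per ordered pair
    w = phi * np.where(g == 1, disease.r_het, 1.0) * np.where(g == 2, disease.r_hom, 1.0)
    total = w.sum()
    if total <= 0:
        raise ValueError("degenerate case-pair distribution (all weights zero)")
    return w / total


def simulate_dataset(
    panel: HaplotypePanel,
    pairing: PairingModel,
    disease: DiseaseModel,
    n_cases: int,
    n_controls: int,
    rng: np.random.Generator,
    snp_ids: Sequence[str] | None = None,
) -> GenotypeDataset:
    """Simulate a case-control dataset of minor-allele counts.

    Cases (phenotype 1, first ``n_cases`` rows) draw haplotype pairs from the
    odds-ratio-weighted distribution; controls draw from the base pairing
    law.  Phase is discarded.
    """
    if n_cases < 1 or n_controls < 1:
        raise ValueError("n_cases and n_controls must both be at least 1")
    weights = case_pair_weights(panel, pairing, disease)
    flat = weights.ravel()
    idx = rng.choice(flat.size, size=n_cases, p=flat)
    ci, cj = np.divmod(idx, panel.n_hap)
    case_g = panel.genotypes_from_pairs(ci, cj)
    i, j = _sample_pair_indices(panel, pairing.f_st, n_controls, rng)
    ctrl_g = panel.genotypes_from_pairs(i, j)
    genotypes = np.vstack([case_g, ctrl_g])
    phenotype = np.zeros(n_cases + n_controls, dtype=np.int8)
    phenotype[:n_cases] = 1
    if snp_ids is None:
        snp_ids = [f"SNP{k + 1}" for k in range(panel.q)]
    return GenotypeDataset(genotypes, phenotype, list(snp_ids))
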