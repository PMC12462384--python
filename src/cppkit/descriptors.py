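"""Sequence descriptor engine.

Every peptide is encoded as a fixed-length vector built from up to seven
blocks, each normalized by the chain length L:

``AAC``       20 amino-acid frequencies (counts / L);
``DPC``       400 overlapping dipeptide frequencies (counts / L);
``TPC``       8000 overlapping tripeptide frequencies (counts / L);
``CKSAAGP``   frequencies of ordered pairs of physicochemical residue
              groups separated by k intervening residues, for k = 0..K
              (g^2 * (K+1) entries; 400 with the default 5 groups, K = 15);
``PHYSCHEM``  isoelectric point, net charge at a fixed pH, GRAVY
              (Kyte-Doolittle mean hydropathy), a second hydrophobicity
              scale mean (Eisenberg consensus by default), and average
              molecular mass in daltons;
``ATOMIC``    whole-molecule C, H, N, O, S atom counts divided by L
              (``normnC`` .. ``normnS``);
``LENGTH``    the chain length itself.

With the default configuration the concatenation has dimension
20 + 400 + 8000 + 400 + 5 + 5 + 1 = 8831.  Feature names follow the
``BLOCK_subscript`` scheme (``AAC_A``, ``DPC_AR``, ``TPC_RRR``,
``CKSAAGP_k1_PC.PC``, ``normnN``, ...) and their order is a pure function of
the configuration, so saved models can verify column alignment exactly.

Net charge follows the Henderson-Hasselbalch model: the fractional positive
charge of each basic group (N-terminus and K/R/H side chains) is
``1 / (1 + 10^(pH - pKa))`` and the fractional negative charge of each
acidic group (C-terminus and D/E/C/Y side chains) is
``1 / (1 + 10^(pKa - pH))``.  The isoelectric point is the unique pH in
[0, 14] where the net charge crosses zero, located by bisection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from . import _tables as T
from .errors import CppkitError, SequenceError
from .matrix import FeatureMatrix
from .seqio import LabeledDataset, Peptide

__all__ = [
    "PkaTable",
    "DescriptorConfig",
    "DEFAULT_BLOCKS",
    "kmer_composition",
    "cksaagp",
    "scale_mean",
    "molecular_mass",
    "net_charge",
    "isoelectric_point",
    "atomic_frequencies",
    "featurize",
    "featurize_all",
    "load_config",
]

DEFAULT_BLOCKS = ("AAC", "DPC", "TPC", "CKSAAGP", "PHYSCHEM", "ATOMIC", "LENGTH")
PHYSCHEM_NAMES = ("isoelectric_point", "net_charge", "gravy", "hydrophobicity", "mass")
ATOMIC_NAMES = ("normnC", "normnH", "normnN", "normnO", "normnS")

_AA_INDEX = {aa: i for i, aa in enumerate(T.ALPHABET)}


@dataclass(frozen=True)
class PkaTable:
    """Ionization constants for the charge model.

    ``side_chains`` must cover exactly the ionizable residues: basic K, R, H
    and acidic D, E, C, Y.
    """

    n_term: float = T.DEFAULT_PKA_NTERM
    c_term: float = T.DEFAULT_PKA_CTERM
    side_chains: dict[str, float] = field(
        default_factory=lambda: dict(T.DEFAULT_PKA_SIDE_CHAINS)
    )

    def __post_init__(self) -> None:
        expected = T.BASIC_RESIDUES | T.ACIDIC_RESIDUES
        if set(self.side_chains) != expected:
            raise CppkitError(
                f"side-chain pKa table must cover exactly {sorted(expected)}"
            )
        for value in (self.n_term, self.c_term, *self.side_chains.values()):
            if not 0.0 < value < 14.0:
                raise CppkitError(f"pKa {value} outside (0, 14)")


@dataclass(frozen=True)
class DescriptorConfig:
    """Which blocks to compute and with what parameters.

    The configuration alone determines the ordered feature-name list
    (:meth:`feature_names`), which downstream models treat as a contract.
    ``normalize_by`` selects the denominator of the composition blocks:
    ``"length"`` (default) divides every count by L; ``"windows"`` divides
    by the number of windows of that k-mer / gap size instead.
    """

    blocks: tuple[str, ...] = DEFAULT_BLOCKS
    cksaagp_grouping: dict[str, str] = field(
        default_factory=lambda: dict(T.DEFAULT_GROUPS)
    )
    cksaagp_max_gap: int = 15
    pka_table: PkaTable = field(default_factory=PkaTable)
    gravy_scale: str = "kyte-doolittle"
    hydrophobicity_scale: str = "eisenberg"
    net_charge_ph: float = 7.0
    normalize_by: str = "length"

    def __post_init__(self) -> None:
        known = set(DEFAULT_BLOCKS)
        unknown = [b for b in self.blocks if b not in known]
        if unknown:
            raise CppkitError(f"unknown blocks {unknown}; valid: {sorted(known)}")
        if len(set(self.blocks)) != len(self.blocks):
            raise CppkitError("duplicate blocks in configuration")
        pooled = "".join(self.cksaagp_grouping.values())
        if sorted(pooled) != sorted(T.ALPHABET):
            raise CppkitError(
                "cksaagp grouping must partition the 20 canonical residues"
            )
        if self.cksaagp_max_gap < 0:
            raise CppkitError("cksaagp_max_gap must be >= 0")
        for scale in (self.gravy_scale, self.hydrophobicity_scale):
            if scale not in T.SCALES:
                raise CppkitError(
                    f"unknown scale {scale!r}; registered: {sorted(T.SCALES)}"
                )
        if not 0.0 <= self.net_charge_ph <= 14.0:
            raise CppkitError("net_charge_ph outside [0, 14]")
        if self.normalize_by not in {"length", "windows"}:
            raise CppkitError("normalize_by must be 'length' or 'windows'")

    @property
    def n_groups(self) -> int:
        return len(self.cksaagp_grouping)

    def block_dimension(self, block: str) -> int:
        g, K = self.n_groups, self.cksaagp_max_gap
        return {
            "AAC": 20,
            "DPC": 400,
            "TPC": 8000,
            "CKSAAGP": g * g * (K + 1),
            "PHYSCHEM": 5,
            "ATOMIC": 5,
            "LENGTH": 1,
        }[block]

    @property
    def dimension(self) -> int:
        return sum(self.block_dimension(b) for b in self.blocks)

    def block_names(self, block: str) -> list[str]:
        if block == "AAC":
            return [f"AAC_{a}" for a in T.ALPHABET]
        if block == "DPC":
            return [f"DPC_{a}{b}" for a in T.ALPHABET for b in T.ALPHABET]
        if block == "TPC":
            return [
                f"TPC_{a}{b}{c}"
                for a in T.ALPHABET
                for b in T.ALPHABET
                for c in T.ALPHABET
            ]
        if block == "CKSAAGP":
            groups = list(self.cksaagp_grouping)
            return [
                f"CKSAAGP_k{k}_{g1}.{g2}"
                for k in range(self.cksaagp_max_gap + 1)
                for g1 in groups
                for g2 in groups
            ]
        if block == "PHYSCHEM":
            return list(PHYSCHEM_NAMES)
        if block == "ATOMIC":
            return list(ATOMIC_NAMES)
        if block == "LENGTH":
            return ["length"]
        raise CppkitError(f"unknown block {block!r}")

    @property
    def feature_names(self) -> list[str]:
        names: list[str] = []
        for block in self.blocks:
            names.extend(self.block_names(block))
        return names

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "blocks": list(self.blocks),
            "cksaagp_grouping": dict(self.cksaagp_grouping),
            "cksaagp_max_gap": self.cksaagp_max_gap,
            "pka_table": {
                "n_term": self.pka_table.n_term,
                "c_term": self.pka_table.c_term,
                "side_chains": dict(self.pka_table.side_chains),
            },
            "gravy_scale": self.gravy_scale,
            "hydrophobicity_scale": self.hydrophobicity_scale,
            "net_charge_ph": self.net_charge_ph,
            "normalize_by": self.normalize_by,
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_dict(cls, payload: dict) -> "DescriptorConfig":
        payload = dict(payload)
        if "blocks" in payload:
            payload["blocks"] = tuple(payload["blocks"])
        if "pka_table" in payload and isinstance(payload["pka_table"], dict):
            payload["pka_table"] = PkaTable(**payload["pka_table"])
        return cls(**payload)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DescriptorConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def load_config(path: str | Path | None = None) -> DescriptorConfig:
    """Load a YAML configuration, or the packaged default when ``path`` is None."""
    if path is not None:
        return DescriptorConfig.from_yaml(path)
    ref = resources.files("cppkit").joinpath("data/default_config.yaml")
    return DescriptorConfig.from_dict(yaml.safe_load(ref.read_text()))


def _encode(sequence: str) -> np.ndarray:
    try:
        return np.array([_AA_INDEX[c] for c in sequence], dtype=np.intp)
    except KeyError as exc:
        raise SequenceError(f"non-canonical residue {exc.args[0]!r}") from exc


def _seq(p: Peptide | str) -> str:
    return p.sequence if isinstance(p, Peptide) else p


def kmer_composition(
    p: Peptide | str, k: int, normalize_by: str = "length"
) -> np.ndarray:
    """Frequencies of all 20^k overlapping k-mers, lexicographic order.

    Entry for k-mer m is (count of overlapping occurrences of m) divided by
    the chain length L (or by the window count L-k+1 with
    ``normalize_by='windows'``).
    """
    if k not in (1, 2, 3):
        raise CppkitError("k must be 1, 2 or 3")
    seq = _seq(p)
    codes = _encode(seq)
    L = len(codes)
    out = np.zeros(20**k)
    if L >= k:
        idx = codes[: L - k + 1].copy()
        for j in range(1, k):
            idx = idx * 20 + codes[j : L - k + 1 + j]
        np.add.at(out, idx, 1.0)
    denom = L if normalize_by == "length" else max(L - k + 1, 1)
    return out / denom


def cksaagp(
    p: Peptide | str,
    grouping: dict[str, str] | None = None,
    max_gap: int = 15,
    normalize_by: str = "length",
) -> np.ndarray:
    """Composition of k-spaced amino-acid group pairs for gaps k = 0..max_gap.

    For each gap k and ordered group pair (G1, G2) the entry counts
    positions i with residue i in G1 and residue i+k+1 in G2, divided by L.
    Gap slices with k >= L-1 have no index pairs and are all zero.
    """
    grouping = grouping if grouping is not None else T.DEFAULT_GROUPS
    pooled = "".join(grouping.values())
    if sorted(pooled) != sorted(T.ALPHABET):
        raise CppkitError("grouping must partition the 20 canonical residues")
    seq = _seq(p)
    L = len(seq)
    g = len(grouping)
    residue_group = {}
    for gi, members in enumerate(grouping.values()):
        for aa in members:
            residue_group[aa] = gi
    codes = np.array([residue_group[c] for c in seq], dtype=np.intp)
    out = np.zeros(g * g * (max_gap + 1))
    for k in range(max_gap + 1):
        span = L - k - 1
        if span <= 0:
            continue
        pair_idx = k * g * g + codes[:span] * g + codes[k + 1 :]
        denom = L if normalize_by == "length" else span
        np.add.at(out, pair_idx, 1.0 / denom)
    return out


def scale_mean(p: Peptide | str, scale: str | dict[str, float]) -> float:
    """Arithmetic mean of a per-residue scale over the chain.

    With the Kyte-Doolittle scale this is the GRAVY index.
    """
    table = T.SCALES[scale] if isinstance(scale, str) else scale
    seq = _seq(p)
    missing = {c for c in seq if c not in table}
    if missing:
        raise CppkitError(f"scale lacks values for {sorted(missing)}")
    return float(np.mean([table[c] for c in seq]))


def _molecule_formula(seq: str) -> np.ndarray:
    """Elemental formula (C,H,N,O,S) of the whole peptide molecule."""
    counts = np.zeros(5)
    for c in seq:
        counts += T.FORMULAS[c]
    # each peptide bond releases one water
    counts -= np.array(T.WATER_FORMULA, dtype=float) * (len(seq) - 1)
    return counts


def molecular_mass(p: Peptide | str) -> float:
    """Average molecular mass in daltons (residue masses + one water)."""
    seq = _seq(p)
    free = sum(T.RESIDUE_FREE_MASS[c] for c in seq)
    return free - T.WATER_MASS * (len(seq) - 1)


def net_charge(
    p: Peptide | str, ph: float = 7.0, table: PkaTable | None = None
) -> float:
    """Henderson-Hasselbalch net charge at the given pH.

    Sums the fractional protonation of the N-terminus and each K/R/H side
    chain, minus the fractional deprotonation of the C-terminus and each
    D/E/C/Y side chain.
    """
    if not 0.0 <= ph <= 14.0:
        raise CppkitError("ph outside [0, 14]")
    table = table if table is not None else PkaTable()
    seq = _seq(p)
    positive = 1.0 / (1.0 + 10.0 ** (ph - table.n_term))
    negative = 1.0 / (1.0 + 10.0 ** (table.c_term - ph))
    for aa in T.BASIC_RESIDUES:
        n = seq.count(aa)
        if n:
            positive += n / (1.0 + 10.0 ** (ph - table.side_chains[aa]))
    for aa in T.ACIDIC_RESIDUES:
        n = seq.count(aa)
        if n:
            negative += n / (1.0 + 10.0 ** (table.side_chains[aa] - ph))
    return positive - negative


def isoelectric_point(p: Peptide | str, table: PkaTable | None = None) -> float:
    """The pH in [0, 14] where the net charge crosses zero, by bisection.

    The charge is a strictly decreasing function of pH that is positive at
    pH 0 (the N-terminus is fully protonated) and negative at pH 14 (the
    C-terminus is fully deprotonated), so the root exists and is unique.
    Iteration continues until |net_charge| < 1e-9.
    """
    table = table if table is not None else PkaTable()
    seq = _seq(p)
    lo, hi = 0.0, 14.0
    assert net_charge(seq, lo, table) > 0 and net_charge(seq, hi, table) < 0
    mid = 7.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        charge = net_charge(seq, mid, table)
        if abs(charge) < 1e-9:
            break
        if charge > 0:
            lo = mid
        else:
            hi = mid
    return mid


def atomic_frequencies(p: Peptide | str) -> np.ndarray:
    """Whole-molecule C, H, N, O, S atom counts divided by the chain length.

    Returned in the order (normnC, normnH, normnN, normnO, normnS).
    """
    seq = _seq(p)
    return _molecule_formula(seq) / len(seq)


def featurize(p: Peptide | str, cfg: DescriptorConfig | None = None) -> np.ndarray:
    """Concatenate the enabled blocks for one peptide, in ``cfg.blocks`` order."""
    cfg = cfg if cfg is not None else DescriptorConfig()
    seq = _seq(p)
    parts: list[np.ndarray] = []
    for block in cfg.blocks:
        if block == "AAC":
            parts.append(kmer_composition(seq, 1, cfg.normalize_by))
        elif block == "DPC":
            parts.append(kmer_composition(seq, 2, cfg.normalize_by))
        elif block == "TPC":
            parts.append(kmer_composition(seq, 3, cfg.normalize_by))
        elif block == "CKSAAGP":
            parts.append(
                cksaagp(seq, cfg.cksaagp_grouping, cfg.cksaagp_max_gap, cfg.normalize_by)
            )
        elif block == "PHYSCHEM":
            parts.append(
                np.array(
                    [
                        isoelectric_point(seq, cfg.pka_table),
                        net_charge(seq, cfg.net_charge_ph, cfg.pka_table),
                        scale_mean(seq, cfg.gravy_scale),
                        scale_mean(seq, cfg.hydrophobicity_scale),
                        molecular_mass(seq),
                    ]
                )
            )
        elif block == "ATOMIC":
            parts.append(atomic_frequencies(seq))
        elif block == "LENGTH":
            parts.append(np.array([float(len(seq))]))
    return np.concatenate(parts)


def featurize_all(
    ds: LabeledDataset, cfg: DescriptorConfig | None = None
) -> FeatureMatrix:
    """Featurize every peptide, preserving row order and label alignment."""
    cfg = cfg if cfg is not None else DescriptorConfig()
    names = cfg.feature_names
    values = np.empty((len(ds), len(names)))
    for i, peptide in enumerate(ds):
        values[i] = featurize(peptide, cfg)
    return FeatureMatrix(ids=ds.ids, names=names, values=values, labels=ds.labels)
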