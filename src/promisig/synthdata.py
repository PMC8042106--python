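"""Synthetic target-pair compound libraries with planted promiscuity signatures.

The generator emulates the statistical structure of target-pair datasets drawn
from a bioactivity database: for every target pair it produces single-target
compounds for target A (ST-A), for target B (ST-B), and dual-target compounds
(DT) active against both.  What separates DT from ST compounds is a planted
*signature substructure*: every DT compound carries the pair's signature
fragment with probability ``carrier_rate`` while ST compounds carry it only
with probability ``leak_rate``.  Two regimes realise the local/global
dichotomy under study:

* ``mode="local"`` — every pair receives a *distinct* fragment; a classifier
  trained on one pair has nothing transferable to learn about another.
* ``mode="global"`` — all pairs share one fragment, so promiscuity has a
  single universal structural cause and models should transfer.

Molecules are built from a fixed pool of drug-like scaffolds decorated with
small substituents, all joined through single attachment points so every
product is chemically valid.  Compounds that do not carry the signature
receive a size-matched *decoy* ring fragment in its place, so the two classes
differ in fragment identity but not in gross molecular size.  Scaffolds,
decorations and decoys are sulfur-free while eleven of the twelve signature
fragments carry sulfur (the twelfth is a fused benzoxazole unreachable from
the background pools), so a signature can never arise by accident — with
``carrier_rate=1, leak_rate=0`` a plain substructure search reproduces the
class labels exactly.

A second, chemistry-free tier (:func:`generate_bitvector_library`) plants the
same carrier/leak structure directly in random bit vectors; it is the fast
route for exercising models and metrics when no atoms are needed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem

from promisig.assembly import TargetPair

__all__ = [
    "Target",
    "Compound",
    "SignatureSpec",
    "LibraryConfig",
    "PairLibrary",
    "BitvectorPairSet",
    "ConfigurationError",
    "GenerationError",
    "AssemblyError",
    "SCAFFOLDS",
    "DECORATIONS",
    "DECOY_FRAGMENTS",
    "SIGNATURE_FRAGMENTS",
    "assemble_molecule",
    "generate_library",
    "generate_bitvector_library",
    "signature_query",
    "write_compound_table",
    "write_target_table",
    "write_smiles_file",
]


class ConfigurationError(ValueError):
    """Invalid library configuration."""


class GenerationError(RuntimeError):
    """Molecule generation failed; the message names the offending fragment."""


class AssemblyError(RuntimeError):
    """Scaffold/fragment attachment produced an invalid molecule."""


# --------------------------------------------------------------------------
# building-block pools
#
# Scaffolds carry 1-3 attachment points written as [*]; decorations and
# signature fragments carry exactly one.  Scaffolds and decorations are
# sulfur-free by construction so that the (mostly sulfur-bearing) signature
# fragments can only enter a molecule by deliberate planting.

SCAFFOLDS: tuple[str, ...] = (
    "[*]c1ccc([*])cc1",              # benzene-1,4-diyl
    "[*]c1cccc([*])c1",              # benzene-1,3-diyl
    "[*]c1ccc([*])cn1",              # pyridine-2,5-diyl
    "[*]c1cnc([*])cn1",              # pyrazine-2,5-diyl
    "[*]c1ccc2ccc([*])cc2c1",        # naphthalene-2,6-diyl
    "[*]c1ccc2ncc([*])cc2c1",        # quinoline-3,7-diyl
    "[*]c1ccc(C([*])=O)cc1",         # aroyl linker
    "[*]c1ccc(N([*])C)cc1",          # N-methylaniline linker
    "[*]c1ccc(OC([*])C)cc1",         # aryl ether linker
    "[*]c1ccc(-c2ccc([*])cc2)cc1",   # biphenyl-4,4'-diyl
    "[*]c1cc([*])cc(C)c1",           # toluene-3,5-diyl
    "[*]c1ccc(CN([*])C)cc1",         # benzylic amine linker
    "[*]C1CCN([*])CC1",              # piperidine-1,4-diyl
    "[*]N1CCN([*])CC1",              # piperazine-1,4-diyl
    "[*]c1cc([*])no1",               # isoxazole-3,5-diyl
    "[*]c1cc([*])n(C)n1",            # N-methylpyrazole-3,5-diyl
    "[*]c1nc([*])co1",               # oxazole-2,4-diyl
    "[*]c1ccc(C([*])([*])C)cc1",     # gem-disubstituted benzylic core
    "[*]c1ccc2c(c1)OCO2",            # benzodioxol-5-yl
    "[*]c1ccc(C(=O)N([*])C)cc1",     # N-methylbenzamide linker
)

DECORATIONS: tuple[str, ...] = (
    "[*]C", "[*]CC", "[*]CCC", "[*]C(C)C", "[*]CC(C)C",
    "[*]F", "[*]Cl", "[*]Br", "[*]C(F)(F)F",
    "[*]O", "[*]OC", "[*]OCC", "[*]OC(C)C", "[*]CO", "[*]CCO",
    "[*]N", "[*]NC", "[*]N(C)C", "[*]CN",
    "[*]C#N", "[*]C(=O)C", "[*]C(=O)OC", "[*]C(=O)N", "[*]C(=O)O",
    "[*]NC(C)=O", "[*]C(=O)NC",
    "[*]c1ccccc1", "[*]Cc1ccccc1", "[*]c1ccncc1",
    "[*]N1CCCC1", "[*]N1CCOCC1", "[*]C1CC1",
)

#: size-matched ring fragments planted wherever a signature is NOT.  They
#: serve two purposes: without them, carrying a signature would make DT
#: compounds systematically larger, so gross size would act as a global
#: promiscuity cue; and they deliberately echo the signature chemotypes
#: (fused azoles, aromatic S-heterocycles, thioethers, sulfonyls, thioamides,
#: N-linked saturated rings) so that element and functional-group composition
#: is class-neutral — only the specific planted substructure separates DT
#: from ST, mirroring congeneric medicinal-chemistry series where actives and
#: inactives share their background chemistry.  None of the decoys contains a
#: signature fragment as a substructure.
DECOY_FRAGMENTS: tuple[str, ...] = (
    "[*]c1ccc2ccccc2c1",             # naphthalen-2-yl
    "[*]C1CCOc2ccccc21",             # chroman-4-yl
    "[*]N1CCc2ccccc2C1",             # 1,2,3,4-tetrahydroisoquinolin-2-yl
    "[*]c1nc2ccccc2s1",              # 1,3-benzothiazol-2-yl
    "[*]c1cc2ccccc2o1",              # 1-benzofuran-2-yl
    "[*]Cc1ccsc1",                   # thiophen-3-ylmethyl
    "[*]c1cnc(C)s1",                 # 2-methyl-1,3-thiazol-5-yl
    "[*]N1CCSC1",                    # 1,3-thiazolidin-3-yl
    "[*]C1CCS(=O)(=O)CC1",           # 1,1-dioxothian-4-yl
    "[*]S(=O)(=O)N(C)C",             # dimethylsulfamoyl
    "[*]c1ccc(S(C)(=O)=O)cc1",       # 4-(methanesulfonyl)phenyl
    "[*]C(=S)N(C)C",                 # dimethylcarbamothioyl
    "[*]N1CCN(C)CC1",                # 4-methylpiperazin-1-yl
    "[*]c1ccc(SC)cc1",               # 4-(methylsulfanyl)phenyl
    "[*]C1CSCC1",                    # thiolan-3-yl
)

#: one distinct fragment per possible local-mode pair, ordered so that
#: neighbouring entries alternate chemotypes (fused aromatics, aliphatic
#: sulfones, thioamides, N-/S-/O-linked rings); every fragment has a close
#: analogue in the decoy pool above
SIGNATURE_FRAGMENTS: tuple[str, ...] = (
    "[*]c1nsc2ccccc12",              # 1,2-benzisothiazol-3-yl
    "[*]C1CCS(=O)(=O)C1",            # sulfolan-3-yl
    "[*]C(=S)N1CCCC1",               # pyrrolidine-1-carbothioyl
    "[*]c1ccc(Br)s1",                # 5-bromothiophen-2-yl
    "[*]N1CCSCC1",                   # thiomorpholin-4-yl
    "[*]c1nc2ccccc2o1",              # 1,3-benzoxazol-2-yl
    "[*]S(=O)(=O)N1CCCC1",           # pyrrolidin-1-ylsulfonyl
    "[*]c1nnc(C)s1",                 # 5-methyl-1,3,4-thiadiazol-2-yl
    "[*]OC1CCSC1",                   # thiolan-3-yloxy
    "[*]c1cc2ccccc2s1",              # 1-benzothiophen-2-yl
)

#: probability that a free attachment point receives a decoration (vs. H)
_DECORATION_FILL = 0.7


# --------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class Target:
    """A protein target with a family label (e.g. kinase, GPCR)."""

    target_id: str
    family: str

    def __post_init__(self) -> None:
        if not self.family:
            raise ValueError("target family must be non-empty")


@dataclass(frozen=True)
class Compound:
    """One molecule with activity annotations relative to an owning pair.

    ``klass`` is ST_A / ST_B / DT; a DT compound is active against exactly the
    pair's two targets, an ST compound against exactly one.
    """

    compound_id: str
    smiles: str
    targets: tuple[str, ...]
    klass: str


@dataclass(frozen=True)
class SignatureSpec:
    """A planted signature substructure and its carrier/leak probabilities."""

    fragment_smiles: str
    carrier_rate: float
    leak_rate: float
    mode: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.leak_rate < self.carrier_rate <= 1.0):
            raise ConfigurationError(
                "need 0 <= leak_rate < carrier_rate <= 1, got "
                f"leak={self.leak_rate}, carrier={self.carrier_rate}"
            )
        if self.mode not in ("local", "global"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        frag = Chem.MolFromSmiles(self.fragment_smiles)
        if frag is None:
            raise ConfigurationError(
                f"signature fragment does not parse: {self.fragment_smiles!r}"
            )
        if sum(1 for a in frag.GetAtoms() if a.GetAtomicNum() == 0) != 1:
            raise ConfigurationError(
                f"signature fragment needs exactly one attachment point: "
                f"{self.fragment_smiles!r}"
            )


@dataclass(frozen=True)
class LibraryConfig:
    """Size, signature regime and seed of a synthetic library.

    Defaults correspond to a minimally qualifying target pair: 50 + 50
    single-target and 100 dual-target compounds, with DT compounds carrying
    the pair signature at rate 0.9 and ST compounds leaking it at rate 0.05.
    """

    n_pairs: int = 2
    n_st_a: int = 50
    n_st_b: int = 50
    n_dt: int = 100
    mode: str = "local"
    carrier_rate: float = 0.9
    leak_rate: float = 0.05
    families: tuple[str, ...] = ("kinase", "GPCR", "protease", "nuclear receptor")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 2:
            raise ConfigurationError("n_pairs must be >= 2")
        if min(self.n_st_a, self.n_st_b, self.n_dt) < 1:
            raise ConfigurationError("class sizes must be >= 1")
        if self.mode not in ("local", "global"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if not self.families:
            raise ConfigurationError("families must be non-empty")
        if self.mode == "local" and self.n_pairs > len(SIGNATURE_FRAGMENTS):
            raise ConfigurationError(
                f"local mode supports at most {len(SIGNATURE_FRAGMENTS)} pairs "
                "(one distinct signature fragment each)"
            )


@dataclass
class PairLibrary:
    """Raw generated compound sets for one target pair."""

    pair: TargetPair
    signature: SignatureSpec
    st_a: list[Compound]
    st_b: list[Compound]
    dt: list[Compound]

    @property
    def compounds(self) -> list[Compound]:
        return list(self.st_a) + list(self.st_b) + list(self.dt)


@dataclass
class BitvectorPairSet:
    """Chemistry-free analogue of a pair library: labelled bit vectors."""

    pair_index: int
    X: np.ndarray          # (n, n_bits) uint8
    klass: list[str]       # ST_A / ST_B / DT per row
    signature_bits: tuple[int, ...]

    @property
    def y(self) -> np.ndarray:
        """Class labels with the global convention DT = +1, ST = -1."""
        return np.where(np.asarray(self.klass) == "DT", 1, -1)


# --------------------------------------------------------------------------
# molecule assembly


def _first_dummy(mol: Chem.Mol) -> int | None:
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 0:
            return atom.GetIdx()
    return None


def _attach(core: Chem.Mol, frag: Chem.Mol) -> Chem.Mol:
    """Join `frag` to `core` through the first attachment point of each."""
    ci = _first_dummy(core)
    fi = _first_dummy(frag)
    if ci is None or fi is None:
        raise AssemblyError("both pieces need an open attachment point")
    combo = Chem.RWMol(Chem.CombineMols(core, frag))
    offset = core.GetNumAtoms()
    c_nbr = combo.GetAtomWithIdx(ci).GetNeighbors()[0].GetIdx()
    f_nbr = combo.GetAtomWithIdx(fi + offset).GetNeighbors()[0].GetIdx()
    combo.AddBond(c_nbr, f_nbr, Chem.BondType.SINGLE)
    for idx in sorted((ci, fi + offset), reverse=True):
        combo.RemoveAtom(idx)
    return combo.GetMol()


def _strip_dummies(mol: Chem.Mol) -> Chem.Mol:
    em = Chem.RWMol(mol)
    for idx in sorted(
        (a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() == 0), reverse=True
    ):
        em.RemoveAtom(idx)
    return em.GetMol()


def assemble_molecule(
    scaffold: str,
    decorations: Sequence[str | None] = (),
    signature: str | None = None,
) -> str:
    """Attach a signature fragment and decorations to a scaffold.

    The signature (if any) is attached to the scaffold's first open point,
    decorations follow in order; a ``None`` decoration leaves its point
    unsubstituted (hydrogen).  Returns the canonical SMILES of the product,
    which contains the signature as a substructure iff one was supplied.
    """
    core = Chem.MolFromSmiles(scaffold)
    if core is None:
        raise AssemblyError(f"scaffold does not parse: {scaffold!r}")
    n_points = sum(1 for a in core.GetAtoms() if a.GetAtomicNum() == 0)
    items: list[str | None] = ([signature] if signature is not None else []) + list(
        decorations
    )
    if len(items) > n_points:
        raise AssemblyError(
            f"scaffold {scaffold!r} has {n_points} attachment points, "
            f"{len(items)} fragments supplied"
        )
    mol = core
    for item in items:
        if item is None:
            # consume one attachment point, leaving hydrogen: mark by moving
            # the dummy to the end of the queue via removal later.  Simplest
            # correct treatment: remember and strip at the end -- but order
            # matters, so replace this dummy with an explicit H now.
            idx = _first_dummy(mol)
            em = Chem.RWMol(mol)
            em.GetAtomWithIdx(idx).SetAtomicNum(1)
            mol = Chem.RemoveHs(em.GetMol(), sanitize=False)
            continue
        frag = Chem.MolFromSmiles(item)
        if frag is None:
            raise AssemblyError(f"fragment does not parse: {item!r}")
        mol = _attach(mol, frag)
    mol = _strip_dummies(mol)
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:  # pragma: no cover - pools are curated
        raise AssemblyError(f"assembly produced an invalid molecule: {exc}") from exc
    return Chem.MolToSmiles(mol)


def signature_query(fragment_smiles: str) -> Chem.Mol:
    """Substructure query for a planted fragment (attachment point removed)."""
    frag = Chem.MolFromSmiles(fragment_smiles)
    if frag is None:
        raise ConfigurationError(f"fragment does not parse: {fragment_smiles!r}")
    query = _strip_dummies(frag)
    Chem.SanitizeMol(query)
    return query


# --------------------------------------------------------------------------
# library generation


def _pair_rng(seed: int, pair_index: int) -> np.random.Generator:
    # one master seed fans out to stable per-pair child streams, so adding
    # pairs never perturbs earlier pairs
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(pair_index,)))


def _build_compound(
    rng: np.random.Generator, carries: bool, fragment: str
) -> str:
    scaffold = SCAFFOLDS[rng.integers(len(SCAFFOLDS))]
    n_points = scaffold.count("[*]")
    # the first attachment point always receives a ring fragment: the pair
    # signature for carriers, a neutral decoy otherwise, so classes differ
    # only in fragment identity, never in gross size
    head = fragment if carries else DECOY_FRAGMENTS[rng.integers(len(DECOY_FRAGMENTS))]
    decorations: list[str | None] = [
        DECORATIONS[rng.integers(len(DECORATIONS))]
        if rng.random() < _DECORATION_FILL
        else None
        for _ in range(n_points - 1)
    ]
    try:
        return assemble_molecule(scaffold, decorations, signature=head)
    except AssemblyError as exc:
        raise GenerationError(
            f"failed to assemble molecule with fragment {fragment!r}: {exc}"
        ) from exc


def generate_library(config: LibraryConfig) -> list[PairLibrary]:
    """Generate compound sets for every target pair of a library.

    Each pair yields ``n_st_a + n_st_b + n_dt`` compounds.  In local mode the
    pairs receive distinct signature fragments; in global mode all pairs share
    ``SIGNATURE_FRAGMENTS[0]``.  Identical config (including seed) reproduces
    the library byte for byte.
    """
    libraries = []
    for p in range(config.n_pairs):
        fragment = (
            SIGNATURE_FRAGMENTS[p] if config.mode == "local" else SIGNATURE_FRAGMENTS[0]
        )
        spec = SignatureSpec(
            fragment_smiles=fragment,
            carrier_rate=config.carrier_rate,
            leak_rate=config.leak_rate,
            mode=config.mode,
        )
        family = config.families[p % len(config.families)]
        pair = TargetPair(
            target_a=Target(f"T{2 * p:03d}", family),
            target_b=Target(f"T{2 * p + 1:03d}", family),
            pair_id=f"P{p:03d}",
        )
        rng = _pair_rng(config.seed, p)
        sets: dict[str, list[Compound]] = {"ST_A": [], "ST_B": [], "DT": []}
        plan = [
            ("ST_A", config.n_st_a, config.leak_rate, (pair.target_a.target_id,)),
            ("ST_B", config.n_st_b, config.leak_rate, (pair.target_b.target_id,)),
            (
                "DT",
                config.n_dt,
                config.carrier_rate,
                (pair.target_a.target_id, pair.target_b.target_id),
            ),
        ]
        for klass, count, rate, targets in plan:
            for i in range(count):
                carries = bool(rng.random() < rate)
                smiles = _build_compound(rng, carries, fragment)
                sets[klass].append(
                    Compound(
                        compound_id=f"{pair.pair_id}-{klass}-{i:04d}",
                        smiles=smiles,
                        targets=targets,
                        klass=klass,
                    )
                )
        libraries.append(
            PairLibrary(
                pair=pair,
                signature=spec,
                st_a=sets["ST_A"],
                st_b=sets["ST_B"],
                dt=sets["DT"],
            )
        )
    return libraries


def generate_bitvector_library(
    config: LibraryConfig,
    n_bits: int = 256,
    signature_width: int = 4,
    background_rate: float = 0.1,
) -> list[BitvectorPairSet]:
    """Chemistry-free tier: plant the carrier/leak structure in bit vectors.

    Pair ``p`` owns a block of ``signature_width`` signature bits (disjoint
    across pairs in local mode, shared in global mode).  A DT vector switches
    its pair's signature block on with probability ``carrier_rate``, an ST
    vector with ``leak_rate``; all remaining background bits are set
    independently with probability ``background_rate``.
    """
    blocks = {}
    for p in range(config.n_pairs):
        start = p * signature_width if config.mode == "local" else 0
        blocks[p] = tuple(range(start, start + signature_width))
    needed = 1 + max(b for bits in blocks.values() for b in bits)
    if n_bits < needed:
        raise ConfigurationError(
            f"n_bits={n_bits} too small for the signature blocks (need >= {needed})"
        )
    sets = []
    for p in range(config.n_pairs):
        rng = _pair_rng(config.seed, p)
        sig = np.array(blocks[p])
        background = np.setdiff1d(np.arange(n_bits), sig)
        rows = []
        klass = []
        plan = [
            ("ST_A", config.n_st_a, config.leak_rate),
            ("ST_B", config.n_st_b, config.leak_rate),
            ("DT", config.n_dt, config.carrier_rate),
        ]
        for name, count, rate in plan:
            for _ in range(count):
                v = np.zeros(n_bits, dtype=np.uint8)
                if rng.random() < rate:
                    v[sig] = 1
                v[background[rng.random(background.size) < background_rate]] = 1
                rows.append(v)
                klass.append(name)
        sets.append(
            BitvectorPairSet(
                pair_index=p,
                X=np.stack(rows),
                klass=klass,
                signature_bits=blocks[p],
            )
        )
    return sets


# --------------------------------------------------------------------------
# tabular output


def write_compound_table(path: str | Path, libraries: Iterable[PairLibrary]) -> None:
    """One row per (compound, annotated target): id, SMILES, target, class."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["compound_id", "smiles", "target_id", "class"])
        for lib in libraries:
            for c in lib.compounds:
                for t in c.targets:
                    writer.writerow([c.compound_id, c.smiles, t, c.klass])


def write_target_table(path: str | Path, libraries: Iterable[PairLibrary]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["target_id", "family"])
        seen = set()
        for lib in libraries:
            for t in (lib.pair.target_a, lib.pair.target_b):
                if t.target_id not in seen:
                    seen.add(t.target_id)
                    writer.writerow([t.target_id, t.family])


def write_smiles_file(path: str | Path, libraries: Iterable[PairLibrary]) -> None:
    with open(path, "w") as fh:
        for lib in libraries:
            for c in lib.compounds:
                fh.write(f"{c.smiles}\t{c.compound_id}\n")
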