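"""SVM prediction decomposition: per-feature weights fc and atom weights fw.

For a Tanimoto-kernel SVM with support vectors x(i), dual coefficients
y(i)*lambda(i) and bias b, the contribution of fingerprint feature d to the
prediction of a compound x is

    fc(x, d) = sum_i  y(i) lambda(i) x(i)_d x_d
               / ( <x(i), x(i)> + <x, x> - <x(i), x> )

i.e. the Tanimoto kernel value split over the bits shared between x and each
support vector.  Summing fc over all bits recovers the decision value minus
the bias exactly, which ties every attribution to the prediction it explains.
Positive weights are evidence for the dual-target (DT) class, negative for
single-target (ST).

Feature weights are pushed down to atoms through the fingerprint's
feature-atom index: every occurrence of feature d distributes
fc(d) / (n_atoms(occurrence) * n_occ(d)) to each of its atoms, so the total
atom weight of a molecule equals the total feature weight (bias excluded --
it has no feature and is reported alongside instead).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from promisig.features import FeatureAtomIndex, Fingerprint
from promisig.models import FittedClassifier

__all__ = [
    "FeatureWeights",
    "AtomWeights",
    "UnsupportedModelError",
    "AttributionConsistencyError",
    "feature_weight",
    "feature_contributions",
    "map_to_atoms",
    "render_map",
    "substructure_weight_percentile",
]


class UnsupportedModelError(TypeError):
    """Feature weighting applies to Tanimoto-kernel SVM models only."""


class AttributionConsistencyError(ValueError):
    """A set bit with nonzero weight is missing from the feature-atom index."""


@dataclass
class FeatureWeights:
    """Signed per-feature weights fc(x, d) for one compound under one model.

    ``fc`` maps set bits to weights; unset bits are identically zero.  The
    stored decision value satisfies ``decision = sum(fc.values()) + bias`` up
    to numerical round-off.
    """

    fc: dict[int, float]
    bias: float
    decision: float
    compound_id: str = ""
    model_pair_id: str = ""

    @property
    def total(self) -> float:
        return float(sum(self.fc.values()))


@dataclass
class AtomWeights:
    """Per-atom weights fw(a) for one molecule; conserves the fc total."""

    weights: np.ndarray
    bias: float
    compound_id: str = ""

    @property
    def total(self) -> float:
        return float(self.weights.sum())


def _require_svm(model: FittedClassifier) -> None:
    if model.algorithm != "svm" or model.support_vectors is None:
        raise UnsupportedModelError(
            "feature weighting needs a fitted Tanimoto-kernel SVM"
        )


def _fc_vector(model: FittedClassifier, x_bits: np.ndarray) -> np.ndarray:
    """fc over all bits as a dense vector (zero at unset bits)."""
    x = x_bits.astype(np.float64)
    sv = model.support_vectors.astype(np.float64)
    inter = sv @ x                      # <x(i), x>
    denom = sv.sum(axis=1) + x.sum() - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(denom > 0, model.dual_coef / denom, 0.0)
    return (scale @ sv) * x


def feature_weight(model: FittedClassifier, x: Fingerprint, d: int) -> float:
    """fc(x, d) for a single feature; zero whenever bit d is unset in x."""
    _require_svm(model)
    if x.n_bits != model.n_bits:
        raise ValueError("fingerprint length does not match the model")
    if not x.bits[d]:
        return 0.0
    return float(_fc_vector(model, x.bits)[d])


def feature_contributions(
    model: FittedClassifier,
    x: Fingerprint,
    compound_id: str = "",
) -> FeatureWeights:
    """All per-feature weights of one compound plus the model bias.

    The per-bit sum reconstructs the kernel expansion, so
    ``sum_d fc(x, d) + bias`` equals the SVM decision value.
    """
    _require_svm(model)
    if x.n_bits != model.n_bits:
        raise ValueError("fingerprint length does not match the model")
    vec = _fc_vector(model, x.bits)
    fc = {int(d): float(vec[d]) for d in x.on_bits}
    return FeatureWeights(
        fc=fc,
        bias=float(model.intercept),
        decision=float(sum(fc.values()) + model.intercept),
        compound_id=compound_id,
        model_pair_id=model.pair_id,
    )


def map_to_atoms(
    fw_input: FeatureWeights,
    index: FeatureAtomIndex,
    n_atoms: int,
    compound_id: str = "",
) -> AtomWeights:
    """Distribute feature weights onto atoms: fw(a) = sum_d fc(d)/(n_atoms*n_occ).

    Every occurrence of every set feature containing atom ``a`` contributes
    its share; the atom total equals the feature total by construction.
    """
    weights = np.zeros(n_atoms, dtype=np.float64)
    for d, fc_d in fw_input.fc.items():
        if d not in index:
            raise AttributionConsistencyError(
                f"set bit {d} has weight {fc_d} but no atom environments"
            )
        occurrences = index[d]
        n_occ = len(occurrences)
        for occ in occurrences:
            share = fc_d / (occ.n_atoms * n_occ)
            for a in occ.atoms:
                weights[a] += share
    return AtomWeights(
        weights=weights, bias=fw_input.bias, compound_id=compound_id or fw_input.compound_id
    )


def substructure_weight_percentile(
    smiles: str, atom_weights: AtomWeights, query: Chem.Mol
) -> float | None:
    """Rank of a substructure's mean atom weight within the molecule.

    Returns the fraction of atoms outside the matched substructure whose
    weight lies strictly below the substructure's mean weight (1.0 = the
    substructure outranks every other atom), or None when the query does not
    match.  Used to check that planted signature fragments attract the
    highest positive weights.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    matches = mol.GetSubstructMatches(query)
    if not matches:
        return None
    frag_atoms = sorted({a for match in matches for a in match})
    w = atom_weights.weights
    mean_frag = float(w[frag_atoms].mean())
    others = np.delete(w, frag_atoms)
    if others.size == 0:
        return 1.0
    return float(np.mean(others < mean_frag))


def render_map(
    smiles: str,
    atom_weights: AtomWeights,
    path: str,
    size: tuple[int, int] = (350, 350),
):
    """Draw the molecule with a Gaussian placed on each atom, scaled by fw(a).

    Positive weights render on a red gradient (DT evidence), negative on
    blue (ST evidence).  Rendering is best-effort: if the drawing backend is
    unavailable the attribution data are unaffected and None is returned
    with a warning.
    """
    try:
        from rdkit.Chem.Draw import SimilarityMaps, rdMolDraw2D

        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {smiles!r}")
        svg = str(path).lower().endswith(".svg")
        drawer = (
            rdMolDraw2D.MolDraw2DSVG(*size) if svg else rdMolDraw2D.MolDraw2DCairo(*size)
        )
        SimilarityMaps.GetSimilarityMapFromWeights(
            mol,
            [float(v) for v in atom_weights.weights],
            draw2d=drawer,
            colorMap="bwr",  # positive weights red (DT), negative blue (ST)
        )
        drawer.FinishDrawing()
        payload = drawer.GetDrawingText()
        mode = "w" if svg else "wb"
        with open(path, mode) as fh:
            fh.write(payload)
        return path
    except Exception as exc:  # pragma: no cover - backend-dependent
        warnings.warn(f"skipping attribution rendering: {exc}")
        return None
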