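"""Grad-CAM atom attribution for the graph-convolutional classifier.

For a class ``c`` and a graph-conv layer ``l`` the attribution proceeds in
two steps. First, per-kernel weights are formed from the ReLU-clipped
gradients of the predicted class probability ``y^c`` with respect to the
layer's feature map, averaged over the (padded) atom dimension::

    alpha_k = (1/N) sum_n ReLU( d y^c / d F^l[n, k] ),   N = 50

Second, the per-atom attention map is the alpha-weighted sum of the
feature map::

    M^c[n] = sum_k alpha_k * F^l[n, k]

The clipping is applied to the gradients only; the final map is left
unclipped. With ReLU activations the feature maps are nonnegative, so
both class maps are nonnegative as well. Padded atom positions have
all-zero feature maps and therefore score exactly zero.

Gradients are exact partial derivatives computed by the same explicit
backward pass the training loop uses; they account both for the layer's
own pooled contribution to the classifier and for its influence on the
deeper layers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .gcn import ModelParams, _activate, _activate_grad, _softmax, \
    forward_batch, global_average_pool
from .pkfi import ACTIVE_CLASS_INDEX

logger = logging.getLogger(__name__)

#: Normalized scores below this threshold are not drawn in depictions.
DRAW_THRESHOLD = 0.05

CLASS_INDEX = {"positive": ACTIVE_CLASS_INDEX,
               "negative": 1 - ACTIVE_CLASS_INDEX}


@dataclass
class AttentionMap:
    """Per-atom Grad-CAM scores for one class at one layer."""

    layer: int            # 1-based graph-conv layer index
    class_label: str      # "positive" | "negative"
    scores: np.ndarray    # raw scores, length 50 (padded positions are 0)
    n_atoms: int

    @property
    def normalized(self) -> np.ndarray:
        """Scores scaled so the top atom reads 1.0 (display convention)."""
        peak = self.scores.max()
        if peak <= 0:
            return np.zeros_like(self.scores)
        return self.scores / peak


def probabilities_from_layer(graph, params: ModelParams, layer: int,
                             F_l: np.ndarray) -> np.ndarray:
    """Class probabilities with the feature map of ``layer`` replaced.

    The shallower layers are run normally; ``F_l`` substitutes the output
    of layer ``layer`` and everything downstream is recomputed.
    """
    _, fmaps = forward_batch(graph.AF, graph.L, params)
    gaps = [global_average_pool(f) for f in fmaps[:layer - 1]]
    F = F_l
    gaps.append(global_average_pool(F))
    for W in params.weights[layer:]:
        F = _activate(graph.L @ F @ W, params.activation)
        gaps.append(global_average_pool(F))
    h = np.concatenate(gaps, axis=-1)
    return _softmax(h @ params.classifier_w + params.classifier_b)


def class_gradients(params: ModelParams, graph, class_label: str,
                    layer: int) -> np.ndarray:
    """Exact gradient of the class probability w.r.t. a layer's feature map.

    Returns a (50, d_l) matrix of partial derivatives of the softmax
    probability of ``class_label`` with respect to every entry of the
    feature map of graph-conv layer ``layer`` (1-based).
    """
    n_layers = len(params.weights)
    if layer not in range(1, n_layers + 1):
        raise ValueError(f"layer must be in 1..{n_layers}, got {layer}")
    params.validate()
    c = CLASS_INDEX[class_label]

    probs, fmaps, cache = forward_batch(graph.AF, graph.L, params,
                                        keep_cache=True)
    p = probs
    # d y_c / d logits_m = p_c (delta_cm - p_m)
    dlogits = -p[c] * p
    dlogits[c] += p[c]
    dh = params.classifier_w @ dlogits
    offsets = np.cumsum((0,) + params.kernels)
    dgaps = [dh[offsets[l]:offsets[l + 1]] for l in range(n_layers)]

    n_pad = graph.AF.shape[-2]
    # walk back from the deepest layer, accumulating both the pooling path
    # and the through-deeper-layers path
    dF = np.tile(dgaps[-1] / n_pad, (n_pad, 1))
    for l in range(n_layers - 1, layer - 1, -1):
        _, Z = cache["caches"][l]
        dZ = dF * _activate_grad(Z, params.activation)
        dF = graph.L @ dZ @ params.weights[l].T  # L symmetric
        dF += np.tile(dgaps[l - 1] / n_pad, (n_pad, 1))
    return dF


def gradcam_weights(gradients: np.ndarray) -> np.ndarray:
    """Per-kernel weights: atom-averaged ReLU-clipped gradients."""
    if not np.all(np.isfinite(gradients)):
        raise ValueError("non-finite gradients")
    n = gradients.shape[0]
    return np.maximum(gradients, 0.0).sum(axis=0) / n


def gradcam_map(alpha: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Per-atom attention: alpha-weighted sum over the kernel dimension."""
    if alpha.shape[0] != F.shape[-1]:
        raise ValueError("alpha and feature map widths disagree")
    return F @ alpha


def explain(params: ModelParams, graph, layer: int = 3):
    """Positive- and negative-class attention maps for one compound.

    The default layer is the last (third) graph convolution, whose
    receptive field covers three bonds around each atom. Raw scores are
    kept on the returned maps; :attr:`AttentionMap.normalized` applies the
    display scaling (per-compound, per-class max = 1).
    """
    params.validate()
    _, fmaps = forward_batch(graph.AF, graph.L, params)
    F = fmaps[layer - 1]
    maps = []
    for class_label in ("positive", "negative"):
        g = class_gradients(params, graph, class_label, layer)
        alpha = gradcam_weights(g)
        scores = gradcam_map(alpha, F)
        maps.append(AttentionMap(layer=layer, class_label=class_label,
                                 scores=scores, n_atoms=graph.n_atoms))
    return tuple(maps)


_CLASS_COLORS = {"positive": (0.45, 0.82, 0.45),   # green
                 "negative": (0.98, 0.66, 0.28)}   # orange


def render(smiles: str, maps, out_prefix, min_radius: float = 0.15,
           max_radius: float = 0.55, threshold: float = DRAW_THRESHOLD):
    """Write one SVG depiction per class with attention circles.

    Circles are centered on atoms, radius linear in the normalized score
    between ``min_radius`` and ``max_radius``; atoms below ``threshold``
    are not drawn. Positive-class circles are green, negative orange.
    Returns the list of written paths.
    """
    from pathlib import Path

    from rdkit.Chem.Draw import rdMolDraw2D

    from .featurize import prepare_molecule

    mol = prepare_molecule(smiles)
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    written = []
    for amap in maps:
        norm = amap.normalized[:amap.n_atoms]
        highlight = [int(i) for i in np.nonzero(norm >= threshold)[0]]
        radii = {i: float(min_radius + (max_radius - min_radius) * norm[i])
                 for i in highlight}
        colors = {i: _CLASS_COLORS[amap.class_label] for i in highlight}
        drawer = rdMolDraw2D.MolDraw2DSVG(450, 400)
        opts = drawer.drawOptions()
        opts.fillHighlights = True
        rdMolDraw2D.PrepareAndDrawMolecule(
            drawer, mol, highlightAtoms=highlight,
            highlightAtomColors=colors, highlightAtomRadii=radii)
        drawer.FinishDrawing()
        path = out_prefix.parent / f"{out_prefix.name}.{amap.class_label}.svg"
        path.write_text(drawer.GetDrawingText())
        written.append(path)
        logger.info("wrote %s (%d highlighted atoms)", path, len(highlight))
    return written


def attention_json(smiles: str, maps) -> dict:
    """Raw and normalized per-atom scores keyed to canonical atom order."""
    return {
        "smiles": smiles,
        "maps": [
            {
                "layer": m.layer,
                "class": m.class_label,
                "raw": [float(x) for x in m.scores[:m.n_atoms]],
                "normalized": [float(x) for x in m.normalized[:m.n_atoms]],
            }
            for m in maps
        ],
    }
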