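"""2-D manifold embedding of simulated spectra.

Simulates a few thousand spectra from prior draws, builds the 26-element
band-power feature vectors, embeds them with UMAP (neighbors=60,
min_dist=0.1) and colors the embedding by posterior-dominant-rhythm center
frequency and by aperiodic exponent — regions of homogeneous color indicate
parameter regimes producing similar spectral features (model indeterminacy).

Run:  python examples/umap_embedding.py --n 3000 --out scratch/umap.png
"""

import argparse
from pathlib import Path

import numpy as np

from sgmkit.features import first_peak_in_band, fit_spectral_model, umap_features
from sgmkit.forward import FrequencyGrid, SGMParameters, network_response
from sgmkit.inference import PriorBox, sample_prior
from sgmkit.synthetic import make_connectome


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--n", type=int, default=3000)
    parser.add_argument("--n-regions", type=int, default=68)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=Path("scratch/umap.png"))
    args = parser.parse_args()

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import umap

    conn = make_connectome(args.n_regions, seed=args.seed)
    grid = FrequencyGrid.default()
    thetas = sample_prior(PriorBox.default(), args.n, seed=args.seed)

    feats, pdr_cf, exponents = [], [], []
    for theta in thetas:
        psd = network_response(conn, SGMParameters.from_array(theta), grid).global_psd
        feats.append(umap_features(psd, grid))
        ap, peaks = fit_spectral_model(psd, grid)
        peak = first_peak_in_band(peaks)
        pdr_cf.append(peak.center_freq if peak else np.nan)
        exponents.append(ap.exponent)
    feats = np.log10(np.array(feats))

    emb = umap.UMAP(n_neighbors=60, min_dist=0.1, random_state=args.seed).fit_transform(feats)

    fig, axes = plt.subplots(1, 2, figsize=(11, 5))
    for ax, color, label in (
        (axes[0], pdr_cf, "PDR center frequency (Hz)"),
        (axes[1], exponents, "aperiodic exponent"),
    ):
        sc = ax.scatter(emb[:, 0], emb[:, 1], c=color, s=4, cmap="viridis")
        fig.colorbar(sc, ax=ax, label=label)
        ax.set_xlabel("UMAP 1")
        ax.set_ylabel("UMAP 2")
    fig.tight_layout()
    args.out.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(args.out, dpi=150)
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
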