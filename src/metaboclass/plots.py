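"""Figure artifacts: CV box plots, R²/Q² permutation plot, ROC, elimination.

Plots are conveniences for visual inspection; every number they show is
also in the CSV/JSON artifacts, which are the authoritative outputs.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

_COLORS = {"rf": "purple", "pls": "tab:blue", "lda": "brown", "svm": "green"}


def _color(method: str) -> str:
    return _COLORS.get(method, "gray")


def holdout_boxplot(results: dict, scheme: str, path: Path) -> None:
    methods = [m for m in results if scheme in results[m]["cv"]]
    data = [results[m]["cv"][scheme].errors for m in methods]
    fig, ax = plt.subplots(figsize=(5, 4))
    box = ax.boxplot(data, tick_labels=[m.upper() for m in methods], patch_artist=True)
    for patch, m in zip(box["boxes"], methods):
        patch.set_facecolor(_color(m))
    ax.set_ylabel("error rate")
    ax.set_title(f"holdout CV errors ({scheme})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def permutation_plot(results: dict, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    for m, res in results.items():
        if "permutation" not in res:
            continue
        d = res["permutation"]
        c = _color(m)
        ax.scatter(d.perm_correlations, d.perm_r2, marker=".", color=c, alpha=0.6)
        ax.scatter(d.perm_correlations, d.perm_q2, marker="o", facecolors="none",
                   edgecolors=c, alpha=0.6)
        ax.scatter([1.0], [d.r2_actual], marker=".", color=c)
        ax.scatter([1.0], [d.q2_actual], marker="o", facecolors="none", edgecolors=c)
        xc = d.perm_correlations.mean()
        ax.plot([0, 1], [d.r2_intercept, d.r2_actual], color=c, lw=1, label=m.upper())
        ax.plot([0, 1], [d.q2_intercept, d.q2_actual], color=c, lw=1, ls="-.")
        del xc
    ax.axhline(0, color="black", lw=0.5)
    ax.set_xlabel("|correlation with actual labels|")
    ax.set_ylabel("$R^2$ (dots) / $Q^2$ (circles)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def roc_plot(results: dict, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    for m, res in results.items():
        curve = res["roc"]
        ax.plot(curve.points[:, 0], curve.points[:, 1], color=_color(m),
                label=f"{m.upper()} (AUC={curve.auc:.3f})")
    ax.plot([0, 1], [0, 1], color="gray", lw=0.5, ls=":")
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def elimination_plot(results: dict, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    for m, res in results.items():
        if "elimination" not in res:
            continue
        curve = res["elimination"]
        ax.plot(curve.counts, curve.errors, color=_color(m), label=m.upper())
    ax.invert_xaxis()
    ax.set_xlabel("number of variables")
    ax.set_ylabel("error rate")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def write_all(bundle: dict, outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results = bundle["results"]
    holdouts = [s for s in bundle["config"].schemes if s.startswith("holdout")]
    for scheme in holdouts:
        holdout_boxplot(results, scheme, outdir / f"boxplot_{scheme.replace(':', '_')}.png")
    if any("permutation" in r for r in results.values()):
        permutation_plot(results, outdir / "permutation.png")
    roc_plot(results, outdir / "roc.png")
    if any("elimination" in r for r in results.values()):
        elimination_plot(results, outdir / "elimination.png")
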