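"""Human-readable summaries of fitted diet models."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .sampler import PosteriorDraws, combine_sources, compare_spread, summarize


def _fmt(df: pd.DataFrame) -> str:
    try:
        return df.to_markdown(floatfmt=".3f")
    except ImportError:  # markdown rendering needs tabulate; fall back
        return df.to_string(float_format=lambda x: f"{x:.3f}")


def report(
    draws: PosteriorDraws,
    dataset=None,
    truth: np.ndarray | None = None,
    groups: dict | None = None,
    compare: PosteriorDraws | None = None,
    level: float = 0.9,
) -> str:
    """Markdown report of posterior diet-proportion estimates.

    Optional sections: truth-overlay scores (when the simulation truth is
    supplied), post-hoc grouped sources, and a spread comparison against
    a second run (e.g. joint vs single-marker).
    """
    species = draws.meta.get("species", [])
    lines = ["# Diet estimation report", ""]
    lines.append(
        f"Species: {', '.join(species)}  |  markers: "
        f"{draws.meta.get('markers', '?')}  |  grouping: "
        f"{draws.meta.get('grouping', '?')}  |  seed: {draws.seed}"
    )
    lines.append("")

    summ = summarize(draws, levels=(level,))
    diet_rows = [n for n in draws.names if n.startswith(("pi[", "Pi["))]
    lines.append("## Posterior diet proportions")
    lines.append("")
    lines.append(_fmt(summ.loc[diet_rows]))
    lines.append("")

    other = [n for n in draws.names if n not in diet_rows]
    if other:
        lines.append("## Other parameters")
        lines.append("")
        lines.append(_fmt(summ.loc[other]))
        lines.append("")

    if truth is not None:
        truth = np.asarray(truth, dtype=float)
        lines.append("## Recovery against simulation truth")
        lines.append("")
        rows = []
        pct = int(round(100 * level))
        for i, s in enumerate(species):
            name = f"pi[{s}]"
            if name not in draws.names:
                continue
            r = summ.loc[name]
            rows.append(
                {
                    "species": s,
                    "truth": truth[i],
                    "posterior_mean": r["mean"],
                    "abs_error": abs(r["mean"] - truth[i]),
                    f"ci{pct}_covers": bool(
                        r[f"ci{pct}_lo"] <= truth[i] <= r[f"ci{pct}_hi"]
                    ),
                }
            )
        lines.append(_fmt(pd.DataFrame(rows).set_index("species")))
        lines.append("")

    if groups:
        lines.append("## Post-hoc source groups")
        lines.append("")
        g = combine_sources(draws, groups)
        lines.append(_fmt(summarize(g, levels=(level,))))
        lines.append("")

    if compare is not None:
        lines.append("## Posterior-spread comparison (this run vs reference)")
        lines.append("")
        common = compare_spread(draws, compare)
        lines.append(_fmt(common))
        lines.append("")

    return "\n".join(lines)
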