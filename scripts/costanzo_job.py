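"""Optional full-scale residual analysis of an SGA supplement export.

This job reproduces the large-scale numbers (retained-cross count,
per-model residual medians/means, pairwise Cramér–von Mises p-values) on
the published yeast double-mutant supplement — a ~6.6M-row CSV the user
downloads separately (https://boonelab.ccbr.utoronto.ca/supplement/costanzo2009).
It is not part of the default test run; everything desk-scale is covered
by the synthetic generator.

Usage:
    python scripts/costanzo_job.py --input sgadata.csv \
        [--config column_map.json] [--out-dir results/costanzo]

The config file (JSON or YAML) may provide ``column_map`` (input header ->
canonical role) and ``delimiter`` if the export's headers differ from the
defaults in ``genebuffer.sga.DEFAULT_COLUMN_MAP``.
"""

import argparse
import json
from pathlib import Path

from genebuffer import load_crosses, run_pipeline


def run_job(input_path, column_map=None, delimiter=None, out_dir=None,
            fitness_low=0.1, fitness_high=0.9, q_min=0.5):
    """Load a cross table, run the pipeline, return (and optionally write)
    the summary dict."""
    table, n_dropped = load_crosses(input_path, column_map=column_map,
                                    delimiter=delimiter)
    result = run_pipeline(table, fitness_low=fitness_low,
                          fitness_high=fitness_high, q_min=q_min)
    summary = {
        "n_rows_read": len(table) + n_dropped,
        "n_complete": len(table),
        "n_dropped_incomplete": n_dropped,
        "n_retained": result["n_retained"],
        "summaries": {k: v.to_dict() for k, v in result["summaries"].items()},
        "cvm_p_values": result["cvm"],
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "costanzo_summary.json").write_text(json.dumps(summary, indent=2))
        result["table"].to_csv(out / "crosses_augmented.csv", index=False)
    return summary


def main(argv=None):
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--input", required=True)
    parser.add_argument("--config", default=None,
                        help="JSON/YAML with column_map and delimiter")
    parser.add_argument("--out-dir", default="results/costanzo")
    parser.add_argument("--q-min", type=float, default=0.5)
    args = parser.parse_args(argv)
    cfg = {}
    if args.config:
        text = Path(args.config).read_text()
        if args.config.endswith((".yaml", ".yml")):
            import yaml
            cfg = yaml.safe_load(text) or {}
        else:
            cfg = json.loads(text)
    summary = run_job(args.input, column_map=cfg.get("column_map"),
                      delimiter=cfg.get("delimiter"), out_dir=args.out_dir,
                      q_min=args.q_min)
    print(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
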