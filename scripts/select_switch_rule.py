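#!/usr/bin/env python
"""Switching-rule selection: score the rule variants against the free-day times.

For each candidate rule (circadian-modulated vs fixed set points, carried-over
vs reset start levels) the free-running steady cycle of every age column is
compared with that column's vacation bed/risetime.  The variant with the
smallest worst-case error is the packaged default.

Usage:  python scripts/select_switch_rule.py
"""

import rhythmostat as r


def main() -> None:
    scores = r.evaluate_switch_rules()
    scores["err"] = scores[["bedtime_error", "risetime_error"]].max(axis=1)
    by_rule = scores.groupby(["threshold_modulated", "carry_over_start"])["err"].max()
    print("worst-case |steady - vacation| error (h) per rule variant:\n")
    print(by_rule.to_string())
    tm, co = by_rule.idxmin()
    print(f"\nselected default: threshold_modulated={tm}, carry_over_start={co}")
    sel = scores[(scores.threshold_modulated == tm) & (scores.carry_over_start == co)]
    print("\nper-group errors under the selected rule:")
    print(sel[["group", "bedtime_error", "risetime_error"]].to_string(index=False))


if __name__ == "__main__":
    main()
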