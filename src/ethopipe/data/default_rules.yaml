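# Default transition-rule set (evaluation order matters).
# A current phase shorter than min_intervals, flanked by phases in the
# prev/next sets, is replaced by the previous phase's label.
- {prev: [standing, lhu], current: lhd, next: [standing, lhu], min_intervals: 3}
- {prev: [lhd], current: lhu, next: [lhd, standing], min_intervals: 6}
- {prev: [standing], current: lhu, next: [lhd], min_intervals: 6}
- {prev: [standing], current: lhu, next: [standing], min_intervals: 25}
- {prev: [lhd, lhu], current: standing, next: [lhd, lhu], min_intervals: 25}
- {prev: [lhd, lhu, standing], current: absent, next: [lhd, lhu, standing], min_intervals: 50}
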