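"""Personalized seizure detection: leave-one-seizure-out on one participant.

Generates a 4-h recording with three planted focal motor seizures, runs the
parameter-optimized leave-one-seizure-out harness with the desk-scale grid,
and prints the event-level results per fold.
"""

from focalwear.dataset import prepare_participant
from focalwear.detector import reduced_param_grid
from focalwear.scoring import run_intra_subject
from focalwear.synthetic import SyntheticProfile, generate_participant

rec, anns = generate_participant(
    SyntheticProfile("DEMO1"), total_hours=4.0, n_seizures=3, seed=1
)
pdata = prepare_participant(rec, anns)
res = run_intra_subject(pdata, reduced_param_grid(), seed=0)

print(f"best hyperparameters: {res.best_params}")
for sid, report in zip(res.fold_seizure_ids, res.fold_reports):
    print(
        f"  left out {sid}: detected={bool(report.tp)}  FP={report.fp}  "
        f"FAR24={report.far24:.2f}"
    )
agg = res.aggregate
print(
    f"sensitivity {agg['pooled_sensitivity']:.0%}, "
    f"mean FAR24 {agg['mean_far24']:.2f} false alarms per 24 h"
)
print(
    "\nEach fold trains on the 10-min peri-ictal surround of the other"
    "\nseizures and is tested on the whole remaining recording; a detection"
    "\nmeans a predicted event overlapped the left-out seizure within the"
    "\n2-min matching margin."
)
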