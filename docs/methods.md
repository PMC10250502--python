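# Methods

`amdt` is a headless toolkit for adaptive auditory psychophysics. It
implements the computational core of a three-alternative forced-choice
(3-AFC) amplitude-modulation detection test (AMDT): calibrated stimulus
synthesis and mixing, a transformed up-down staircase, a simulated
observer, and the statistics used to validate staircase convergence and
event-marker timing. Everything runs against a deterministic virtual clock,
so complete experiments are reproducible from a seed.

## Stimuli

A modulated tone is synthesized as

    s(t) = (1 + m sin(2π f_mod t)) sin(2π f_c t),    m = 10^(depth/20),

with carrier `f_c` (Hz), modulation rate `f_mod` (Hz) and modulation depth
in dB (0 dB = full modulation, m = 1). For synthesis the index is clamped to
[0, 1] so the envelope stays physical; the *tracked* depth is never clamped,
because adaptive procedures may legitimately start above 0 dB. Every
monaural track is normalized to unit RMS before leveling; a level of
`L` dB then scales the waveform by `10^(L/20)`, making per-channel SPL
calibration a single additive offset (`software level = target SPL −
offset`). Mixing is purely additive into a `(channels, samples)` buffer with
onsets quantized to the nearest sample (half away from zero). Defaults:
44.1 kHz sample rate, 500 ms stimulus duration (consistent with the 1 s
inter-onset grid of the trial timeline). Resampling is polyphase
(band-limited); WAV I/O is 32-bit float RIFF.

## Staircase

The transformed up-down procedure (`n_down`-down-1-up; 3-down-1-up here)
decrements the tracked depth by the current step after `n_down` consecutive
correct answers and increments it after a single error. Step sizes follow a
schedule (default 1 dB, then 0.5 dB) keyed to reversal counts (or trial
counts in `by_trial` mode). Conventions the procedure itself does not fix
had to be chosen:

- a **reversal** is recorded at the trial whose executed step changes
  direction relative to the previous executed step; the first executed step
  records none (standard Levitt bookkeeping);
- the schedule advances as soon as the triggering reversal is recorded, so
  the new step applies from the next executed step;
- no floor/ceiling is applied by default (optional saturating bounds).

Such a staircase equilibrates where `n_down` consecutive correct answers are
as likely as one error, `p^n_down = 1/2`, i.e. at response probability
`0.5^(1/n_down)` (0.794 for 3-down-1-up). The stationary analysis of the
consecutive-correct counter chain gives the same fixed point.

## Observer

Answers are drawn once per trial from an error-function psychometric model

    prob(depth) = ½ [1 + erf((depth − midpoint)/(std √2))],

with defaults `midpoint = −9 dB`, `std = 2 dB`, via
`uniform(0,1) < prob(depth)`. The model is used verbatim, without a 1/3
guessing floor for the 3-AFC geometry — the simulated answer depends only on
depth, not on the target interval — which is what makes closed-form
convergence predictions exact. A guessing-corrected observer
(`guess_rate = 1/3`) is available but off by default. The predicted
convergence depth inverts the model at `0.5^(1/n_down)` with `erfinv`; for
the defaults this gives −7.3613 dB.

## Session design

A trial plays three 500 ms intervals at onsets 0.5 / 1.5 / 2.5 s from trial
start; one interval, chosen per the balanced plan, carries the AM target at
the staircase's current depth and the other two are unmodulated tones at the
same carrier. Start/end markers are emitted at first-stimulus onset and
last-stimulus offset on the virtual clock (1 s inter-trial gap). Per
condition and repetition block the three target positions each occur
`reps_per_position` times (12 by default, 36 trials per block), in shuffled
order; condition order is shuffled per block.

The reference **validation design** (`amdt.config.validation_design`)
simulates 10 participants × 4 conditions (carrier 400/1000 Hz × modulation
5/10 Hz). Each condition is presented in **three** 36-trial blocks with a
single staircase continuing across blocks (108 trials per condition run, 40
runs in total), starting at +6 dB. The three-block structure is essential,
not cosmetic: descending from +6 dB to threshold at 1 dB per three trials
consumes roughly 33 trials, so a single 36-trial block ends right at the
first reversal and cannot contain the six smallest-step reversals the
convergence analysis requires — with 108 trials per run, every run we have
simulated does. The generic `repetitions` knob defaults to 1 for ordinary
use. Participant seeds are `base_seed + participant_index`. The validation
config disables waveform rendering (`render_audio = False`): the logged
quantities are identical either way (asserted in the test suite), and the
convergence statistics do not depend on the audio samples.

## Convergence statistics

For each condition run, the *converged depths* are the depths presented on
the trials spanning the last six reversals recorded while the smallest step
(0.5 dB) was in effect — inclusive from the sixth-from-last qualifying
reversal's trial to the last one's. We report the mean of the per-run window
means (*convergence estimation*), the mean of the per-run population
standard deviations (*convergence variability*), and the population standard
deviation across runs of the per-run means' deviations from the analytic
target (*estimation variability*; translation-invariant in the target).
Population divisors (1/N, 1/M) are used throughout. Window edges
(inclusive/inclusive) and the restriction to smallest-step reversals are
package conventions, stated here because the procedure alone does not fix
them.

At the defaults the validation design lands near −7.3 dB — slightly above
the −7.3613 dB asymptote, as expected for a finite staircase descending from
+6 dB — with per-run window variability around 0.4–0.5 dB, on the scale of
the 0.5 dB terminal step.

## Timing audit

Given per-run, index-aligned marker timestamps `xl(i,j)` and physical onset
timestamps `xs(i,j)`: `diff = xl − xs`; the per-run mean `x_mean(j)` is the
latency; `random error = diff − x_mean(j)` is the jitter (zero-mean per run
by construction); the SEM is the population standard deviation of
`x_mean(j)` across runs. Quartiles of the pooled random error use linear
interpolation between order statistics. Physical onsets can be extracted
from a recorded waveform by a causal moving-average envelope (2 ms window)
crossing a fraction (default 0.25) of its maximum, with a minimum gap
between onsets; the causal window means detected onsets lag but never lead
the signal, keeping localization within ~0.5 ms for tone bursts.
`generate_timing_streams` synthesizes paired streams on the session grid
with injected latency and Gaussian jitter; real-hardware latency and jitter
depend on drivers and physical loopback and are out of scope — the audit is
validated by parameter recovery on synthetic streams (48 events × 10 runs).

## Numerical choices and limitations

- Inverse of the psychometric model via `scipy.special.erfinv`
  (≪ 1e-10 error); convergence probability in closed form.
- Step-size comparisons in the reversal filter use `np.isclose` to absorb
  float noise in logged CSVs.
- Onset quantization: round half away from zero.
- The simulated observer is stationary and memoryless: no lapses, drift,
  learning, or interval bias. Passing validation therefore demonstrates the
  correctness of the adaptive logic and analysis pipeline, not robustness to
  human non-stationarity.
- Real-time playback, device I/O and networked marker transport are out of
  scope; markers live on the virtual clock (an injectable real clock is
  possible since `run_trial` only needs `now`/`advance`).
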