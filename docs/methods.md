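# Methods

## The measurement problem

Wrist-worn accelerometry measures whole-arm activity well but is nearly
blind to distal hand movement — the wrist and finger motion that
matters for hand-function monitoring in rehabilitation. The device this
package models senses that motion magnetically: the user wears a small
permanent-magnet ring on the index finger and a wristband carrying four
3-axis magnetometers on the corners of a 25 × 42 mm board, sampled at
52.6 Hz. When the wrist or fingers move, the ring moves relative to the
board and the local field changes; when the whole arm moves, ring and
board move together and the field at the board is unchanged.

## Differential reading

The Earth's field (≈ 0.25–0.65 gauss) dwarfs the ring's near field at
the board but is spatially uniform over a few centimetres. For each
side of the board we subtract the reading of the magnetometer far from
the ring from the near one, and average the two sides:

    d = ((m_nearL − m_farL) + (m_nearR − m_farR)) / 2 .

This cancels any spatially uniform field *exactly* (including an
arm-rotation-induced apparent rotation of the Earth's field, which is
still common to all four sensors), while the ring's field, falling off
as 1/r³, survives with a strong gradient across the board. Averaging
the two sides makes the signal invariant to which hand wears the
device. All processing stays in raw 16-bit LSB units of the ±4 gauss
range (1 LSB = 8/65536 gauss ≈ 0.122 mG).

## The counting algorithm

One count is meant to correspond to one hand movement, the way one step
registers on a pedometer. A typical hand movement lasts 200–700 ms, an
order of magnitude longer than the 19 ms sampling period, so a real
movement drives the filtered differential reading in a *consistent
direction for many consecutive samples*, while sensor noise produces
only short same-direction runs.

Per axis of the differential reading:

1. causal second-order Butterworth low-pass, cutoff `lp_cutoff`;
2. per-sample change Δ = y[k] − y[k−1]; changes with |Δ| ≤ `threshold`
   are ignored — they neither extend nor break a run;
3. supra-threshold changes with the same sign extend the axis's run;
   an opposite sign restarts it at length 1.

A count fires when two axes simultaneously hold runs of at least
`n_two_axes` samples, or one axis holds a run of at least `n_one_axis`
(single-axis evidence gets the stricter, longer requirement). After a
count all run states are cleared and counting is suppressed until a
triggering axis reverses with a supra-threshold change or 2 s elapse.

The run-length minima come from a *device-level* (not per-user)
calibration: on a recording with no hand movement, filter and threshold
as above, pool the same-direction run lengths over the three axes, and
take their standard deviation σ. Then

    n_two_axes = round(sds_two_axes · σ)   (half away from zero, ≥ 1)
    n_one_axis = n_two_axes + extra_samples_one_axis .

The parameter named like an extra σ-multiple is defined in prose as a
number of *additional samples*; we follow the prose and expose
`one_axis_mode="extra_sds"` as the alternative reading without
endorsing it.

### Parameters (defaults)

| parameter | default | units | role |
|---|---|---|---|
| `lp_cutoff` | 8 | Hz | noise smoothing; `None` = no filter |
| `threshold` | 8 | LSB (≈ 0.98 mG) | minimum per-sample change |
| `sds_two_axes` | 5 | — | σ scale for the two-axis run minimum |
| `extra_samples_one_axis` | 2 | samples | extra run length for one-axis triggers |
| `reset_timeout` | 2.0 | s | post-count suppression timeout |
| `fs` | 52.6 | Hz | device sampling rate |

The 8 Hz / 8 LSB / 5 / 2 operating point is the one selected on in-lab
exercise data (it jointly minimises under-counting of prompted hand
postures and false counts during splinted arm movements); the
`parameter_sweep` helper reproduces that exploration on any labelled
logs.

With the default noise model, a 300 s rest recording yields σ ≈
1.15–1.40 (≈ 800 pooled runs), hence run requirements of 6–7 samples on
two axes and 8–9 on one. We recommend ≥ 300 s of calibration data:
60 s recordings (~130 runs) scatter σ enough to move the rounded
requirement by ±1 either way. Calibration refuses to run with fewer
than 100 observed runs.

## Accelerometry comparator

The conventional upper-extremity "activity count": the sum of absolute
sample-to-sample acceleration changes (summed over the three axes) over
a trailing 0.25 s window (13 samples at 52.6 Hz), then peak detection
on that running sum with a 0.33 g threshold and at most 4 accepted
peaks in any trailing one-second window. A pure refractory gap of
0.25 s cannot implement the stated 4-per-second cap (five impulses
squeezed into one second would yield three accepted peaks, not four),
so the cap is enforced as a sliding-window count. Only differences
enter, so the gravity offset is immaterial. The per-axis-sum convention
follows the activity-counts literature; `change_mode="magnitude"` is
available.

## The testbed simulator

The simulator emulates the robotic rig used to characterise the
counter, so the full stack is testable without hardware.

**Physics.** The ring magnet (N52 disk, 12.7 mm × 3.18 mm, remanence
≈ 1.45 T) is a point dipole with m = Br·V/μ₀ ≈ 0.465 A·m²; fields are
computed with the exact dipole law B = (μ₀/4π)(3(m·r̂)r̂ − m)/r³ (a
5 mm guard radius protects the point approximation). Informal
descriptions of the ring field as an inverse-square decay are replaced
by the exact inverse-cube law; the counter only needs monotone decay.
Sensor output is the dipole field plus the Earth field (default
(0.25, 0.15, −0.40) gauss) in the band frame, plus i.i.d. Gaussian
noise, quantized to integer LSB and clipped to the 16-bit range.

**Kinematics.** Wrist flexion/extension rotates the whole hand about
the wrist axis; finger (MCP) flexion/extension rotates the finger
segment about the MCP joint at `dim1` from the wrist crease, with the
ring at `dim2` (hand sizes: small 8.0/9.0 cm, medium 9.3/10.5 cm,
large 10.5/12.0 cm — anthropometric stand-ins for 5th-percentile
female, mixed-median and 95th-percentile male hands, exposed as
config). Strokes follow a minimum-jerk (bell-shaped velocity) profile
θ(τ) = A(10τ³ − 15τ⁴ + 6τ⁵) with duration T = 1.875·A/v_peak, so the
commanded peak angular speed is met exactly and endpoint velocity and
acceleration vanish. Arm-only movement rotates band and ring rigidly
(constant differential, by construction); the accelerometer sees
rotating gravity plus the tangential acceleration of a ~0.3 m lever
arm, which is what the activity comparator responds to.

**Pose defaults.** Sensor board centre 10 mm proximal / 10 mm dorsal of
the wrist crease; index-finger axis offset 1.8 cm laterally from the
board midline; magnet axis perpendicular to the finger, tilted 45°
between lateral and dorsal. Board pose, lateral offset and magnet
orientation are not knowable from the hardware description and are
exposed as configuration; the defaults were chosen once so the
simulated differential matches the *structure* of the measured device
behaviour — a weak gradient near the neutral pose (so small, slow
movements hover at the noise threshold and are partially missed), a
large swing over a full flexion arc (so 75–90° movements are always
counted for small/medium hands), lower finger- than wrist-movement
detection, and accuracy decreasing with hand size.

**Noise default.** `mag_noise_sd = 10` LSB (~1.2 mG) per axis per
sensor, a realistic effective noise floor for the device's magnetometer
class, chosen so the calibrated run-length σ falls in the 1.0–2.0
sample range bracketing the device's worked values (1.2 and 1.5).

**Protocols.** The characterisation grid sweeps amplitudes 5:5:90° and
peak speeds 20:10:600 °/s, dropping combinations whose minimum-jerk
peak acceleration 1.642·v²/A exceeds the servo cap. The cap default
(≈ 2.40 × 10⁴ °/s²) was reverse-engineered to reproduce the physical
rig's grid size; the closest attainable size is 987 of 1062 — exactly
986 is unreachable for *any* cap because the amplitude-5 cutoff at
270 °/s and the amplitude-20 cutoff at 540 °/s sit at the same cap
value on the 10 °/s speed grid, so the total jumps from 985 to 987.
Movements are classified slow (< 200 °/s), medium (200–400) and fast
(> 400) by peak speed. The in-lab protocols are emulated as 50
prompted posture changes (alternating wrist/finger strokes, 30–60°,
150–350 °/s, 2 s spacing) and 200 splinted arm-only movements.

**Evaluation.** Ground truth records each commanded movement's onset,
offset, amplitude, peak speed, speed class and hand size. A movement
counts as detected if at least one event falls in
[onset, offset + 0.5 s]; counting probability is detected/known per
bin (empty bins are reported as missing, not zero). Detection-based
probability is used rather than raw event ratios because a simulated
stroke whose differential trajectory is non-monotone can re-arm the
detector mid-stroke and fire twice; the physical device shows this only
weakly (~4% over-count for unimpaired users), the simulator more
strongly. Raw event counts remain available for crosstalk/error
analyses (`parameter_sweep`, `intensity`).

## What the simulator does and does not capture

It captures: exact common-mode cancellation, dipole near-field
geometry over three hand sizes, quantization, speed/amplitude/hand-size
structure of counting probability, arm-movement rejection, and
device-level noise calibration. It does not capture: soft-tissue and
band-slip artifacts, environmental magnetic disturbance (moving
ferrous objects, electronics — the source of the ~200 counts/hour
baseline observed in daily life), finger abduction/adduction,
multi-finger kinematics, or human movement variability (decomposed
strokes after stroke, postural drift). Passing the simulated
characterisation therefore validates the algorithmic pipeline and its
parameter logic, not clinical accuracy on human data.

## Numerical choices

- The Butterworth filter runs causally (single forward pass, as on the
  device); its state is initialised to the first sample's steady state,
  so a constant input incurs no startup transient. Streaming and batch
  paths use the same direct-form-II-transposed recurrence and produce
  identical outputs.
- Scaled-σ rounding is half-away-from-zero ("closest integer").
- Run comparisons are ≥ (a run of exactly n samples triggers).
- If both triggers would fire at one sample, the event is recorded as
  `two_axes`.
- Sub-threshold changes never expire a run; runs end only by reversal,
  a count, or a recording gap. Gaps longer than 3 sample periods reset
  filter and run state with a warning; samples are never interpolated.
- The 2 s timeout applies to post-count suppression only.
- Simulated logs are bit-reproducible given the noise seed; all
  randomness flows from `numpy.random.default_rng(seed)`.

## Problem sizes

The full simulated characterisation (2 movement types × 3 hand sizes ×
987 movements, ≈ 71 k samples per condition) runs in a few seconds; the
test suite and the acceptance script each complete in well under a
minute on one CPU. Calibration uses 300 s of simulated rest.
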