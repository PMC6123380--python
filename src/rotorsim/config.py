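"""Package-wide default constants.

Values marked "calibrated" were produced by the package's own calibration
routines (see ``monodomain.calibrate_conductivity``) against the clinical
conduction-velocity target and then frozen here as defaults.
"""

#: longitudinal CV calibration target, cm/s (clinical AF mapping range 38-54)
TARGET_CV_CM_S = 43.39

#: calibrated longitudinal diffusivity on the 4.5 cm uniform slab with the
#: chronic-AF ionic variant at h = 350 µm, dt = 0.02 ms (cm²/s)
DEFAULT_SIGMA_L = 1.17861

#: CV anisotropy ratio (longitudinal:transverse) = 2:1, i.e. sigma ratio 4:1
DEFAULT_SIGMA_RATIO = 4.0

#: conductivity scaling at fibrotic nodes (longitudinal, transverse)
FIBROTIC_SCALE_L = 0.7
FIBROTIC_SCALE_T = 0.3

#: milder fibrotic conductivity scaling used with the reduced model at its
#: coarser default spacing, where the full scaling would produce numerical
#: (rather than physiological) conduction block
REDUCED_FIBROTIC_SCALE_L = 0.8
REDUCED_FIBROTIC_SCALE_T = 0.5

#: admissible plane-wave CV band through fibrotic patient-like sheets, cm/s
FIBROTIC_CV_BAND = (15.18, 47.81)

#: stimulus conversion: pA/pF of depolarizing current per mA/cm² of
#: transmembrane stimulus (surface-to-volume / capacitance convention chosen
#: so the standard 0.3 mA/cm² amplitude is ~2x diastolic threshold)
STIM_GAIN_PA_PF_PER_MA_CM2 = 100.0

#: local-activation-time detection threshold, mV (upward crossing)
LAT_THRESHOLD_MV = -60.0

#: default integrator step for the detailed model, ms
DEFAULT_DT_MS = 0.02
#: default integrator step for the reduced model, ms
DEFAULT_DT_REDUCED_MS = 0.1
#: default movie snapshot interval, ms
DEFAULT_SNAPSHOT_MS = 5.0

#: rotor persistence filter
MIN_ROTATIONS = 2.0
MIN_DURATION_MS = 200.0
ANALYSIS_WINDOW_MS = 1000.0

#: trajectory linking
MAX_LINK_MM = 3.0
MAX_GAP_FRAMES = 2
ROTATION_PROBE_RADIUS_MM = 2.0
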