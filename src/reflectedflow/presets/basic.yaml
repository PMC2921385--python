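# "basic" parameter set: gentle auxin-dependent inhibition of PIN1 expression
# (taproot-like transport behaviour).
#
# Provenance: alpha = 1 anchors the influx at which the stationary 1D pattern
# is compared against digitized DR5 staining; K0 = 0.1 anchors the active-
# transport scale against which inhibitor treatments are measured (extra
# small maxima for K0 in ~[0.05, 0.08], two maxima below ~0.05); T = 0.1 is
# the Division Factor synthesis steepness anchor.  All remaining values were
# calibrated once, coordinatewise, so that the reflected-flow regime holds:
# a stable stationary auxin maximum detached from the root end at alpha = 1
# and N = 50, with the PIN1-degradation threshold q3 between the interior
# and boundary stationary auxin levels.
name: basic
auxin:
  alpha: 1.0       # anchor (cu/tu)
  Kd: 0.014        # calibrated (1/tu)
  D: 1.0           # calibrated (1/tu)
  K0: 0.1          # anchor (1/(cu tu))
  k1: 1.0          # calibrated (cu/tu)
  q1: 0.1          # calibrated (cu)
  q2: 1.0          # calibrated (cu)
  h1: 1.0          # calibrated
  k2: 0.02         # calibrated (1/tu)
  q3: 2.2          # calibrated (cu)
  h2: 8.0          # calibrated
division_factor:
  beta: 1.0        # calibrated (cu/tu)
  T: 0.1           # anchor (cu)
  kdeg: 0.03       # calibrated (1/tu)
  q4: 1.3          # calibrated (cu)
  q5: 3.0          # calibrated (cu)
  h3: 4.0          # calibrated
  h4: 4.0          # calibrated
  D_DivF: 0.3      # calibrated (1/tu)
cell_cycle:
  K_growth: 0.002  # calibrated (length/tu); growth phase ~400 tu
  r_min: 1.8       # calibrated (length)
  r0: 1.0          # calibrated (length)
  gp_shape: {k_gp: 0.05, h_gp: 20.0}
  ip_shape: {k_ip: 0.02, q_lo: 0.8, q_hi: 1.3, h_lo: 3.0, h_hi: 8.0}
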