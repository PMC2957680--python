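# Lumped baroreflex model of the human cardiovascular control system:
# heart rate x1 (bpm) and arterial blood pressure x2 (mm Hg) coupled through
# Hill-type baroreflex feedback, in dimensionless time (one time unit equals
# the sympathetic delay, hence the unit delay d1).  A small sinusoidal term
# driven by the breathing rate mimics respiration.
#
# Initial conditions are NOT part of the published parameter set; the values
# below assume the system starts at the uncontrolled operating point
# x1(0) = h0, x2(0) = p0.

[states]
x1 = 100.0   # heart rate, starts at the uncontrolled heart rate h0
x2 = 100.0   # arterial pressure, starts at the mean arterial pressure p0

[parameters]
h0 = 100.0      # uncontrolled heart rate (bpm)
p0 = 100.0      # mean arterial blood pressure (mm Hg)
alpha = 15.0    # sympathetic effect on peripheral resistance
beta = 10.0     # sympathetic control of heart rate
nu = 9.63       # strength of vagal tone
delta = 0.8     # relaxation rate (1/s)
gamma = 0.2     # damping of vagal activity on the sympathetic tone
mu = 0.18       # pressure gain, nominally 3/(2 + alpha)
A1 = 0.0        # respiration amplitude entering the delayed baroreflex term
A2 = 0.003      # respiration amplitude entering the instantaneous term
f_r = 0.17      # breathing rate (Hz)
tau = 3.0       # sympathetic time delay (s); enters only via f_r*tau
phi = 3.14      # phase lag of the respiratory forcing
n_hill = 8.0    # Hill exponent of the baroreflex sigmoid
eps_h = 1.0     # relative time coefficient, heart rate
eps_p = 3.0     # relative time coefficient, blood pressure

[delays]
d1 = 1.0        # unit delay: time is measured in units of the sympathetic delay

[equations]
# g1 = 1/(1 + (x2(t-1)/p0 + r1)^n),  r1 = A1*sin(2*pi*f_r*tau*(t-1) - phi)
# g2 = 1 - 1/(1 + (x2(t)/p0 + r2)^n), r2 = A2*sin(2*pi*f_r*tau*t - phi)
dx1/dt = h0/eps_h * (beta * (1/(1 + (x2@d1/p0 + A1*sin(6.283185307179586*f_r*tau*(t - 1) - phi))^n_hill)) / (1 + gamma * (1 - 1/(1 + (x2/p0 + A2*sin(6.283185307179586*f_r*tau*t - phi))^n_hill))) - nu * (1 - 1/(1 + (x2/p0 + A2*sin(6.283185307179586*f_r*tau*t - phi))^n_hill))) + delta/eps_h * (h0 - x1)
dx2/dt = mu*p0/(eps_p*h0) * x1 - x2 / (eps_p * (1 + alpha * (1/(1 + (x2@d1/p0 + A1*sin(6.283185307179586*f_r*tau*(t - 1) - phi))^n_hill))))

[options]
t0 = 0.0
sampling = 0:200:0.02
epsilon = 1e-3
iteration_limit = 20
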