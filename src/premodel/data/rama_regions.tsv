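# Rectangular Ramachandran region grid (degrees).
# Columns: class, phi_min, phi_max, psi_min, psi_max.
# A (phi, psi) pair is classified by the first class (in the order
# most_favored > additional_allowed > generously_allowed) with a matching
# rectangle; unmatched pairs are disallowed. The rectangles approximate the
# classical core/allowed contours (beta / polyproline, right-handed alpha,
# left-handed alpha); different checkers draw these contours differently, so
# fractions are comparable but not identical across tools.
most_favored	-170	-50	90	180
most_favored	-90	-35	-70	-15
additional_allowed	-180	-20	60	180
additional_allowed	-180	-20	-180	-150
additional_allowed	-160	-20	-90	10
additional_allowed	30	100	-20	90
generously_allowed	-180	0	-180	180
generously_allowed	20	120	-40	100
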