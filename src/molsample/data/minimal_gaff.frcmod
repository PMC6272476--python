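Minimal AMBER/GAFF-style parameter set bundled with molsample.
Values follow the published GAFF tables for the covered types (C/N/O/S/P/H,
halogens, common metal cations); polar hydrogens carry a small nonzero vdW
radius (0.60 A) so that the pair-specific hydrogen-bond contact range
[sum(r*)-0.5, sum(r*)+0.1] is well defined. External AMBER parm/frcmod files
override these entries.
MASS
hc 1.008
h1 1.008
ha 1.008
hn 1.008
ho 1.008
hs 1.008
c  12.01
c1 12.01
c2 12.01
c3 12.01
ca 12.01
n  14.01
n3 14.01
nb 14.01
o  16.00
oh 16.00
os 16.00
s  32.06
p  30.97
f  19.00
cl 35.45
br 79.90
i  126.9
Zn 65.38
Mg 24.31
Ca 40.08
Na 22.99
K  39.10
Fe 55.85
Mn 54.94

BOND
c3-c3  303.1  1.535
c3-hc  337.3  1.092
c3-h1  335.9  1.093
c3-oh  314.1  1.426
c3-os  301.5  1.439
oh-ho  369.6  0.974
c3-n   330.6  1.460
c3-n3  320.6  1.470
n3-hn  394.1  1.018
c -o   648.0  1.214
c -oh  466.4  1.306
c -os  411.3  1.343
c -n   478.2  1.345
n -hn  410.2  1.009
c -c3  328.3  1.508
c -ca  349.7  1.487
ca-ca  478.4  1.387
ca-ha  344.3  1.087
ca-c3  323.5  1.513
ca-oh  386.1  1.362
ca-nb  483.1  1.342
c2-c2  589.7  1.324
c2-c3  328.3  1.508
c2-ha  347.2  1.085
c3-f   363.8  1.344
c3-cl  232.4  1.786
c3-br  194.5  1.944
c3-s   237.2  1.810

ANGLE
c3-c3-c3  63.21  110.63
c3-c3-hc  46.37  110.05
hc-c3-hc  39.43  108.35
h1-c3-h1  39.18  109.55
c3-c3-h1  46.36  110.07
c3-oh-ho  47.09  107.26
h1-c3-oh  50.97  110.26
hc-c3-oh  50.97  110.26
c3-c3-oh  67.72  109.43
c3-c3-os  67.78  107.97
h1-c3-os  50.84  109.78
c3-os-c3  62.40  112.45
ca-ca-ca  67.18  119.97
ca-ca-ha  48.46  120.01
ca-ca-c3  63.84  120.63
ca-ca-oh  69.85  119.94
ca-oh-ho  48.85  109.90
ca-c3-hc  47.21  110.15
ca-c3-h1  47.21  110.15
ca-c3-c3  63.25  112.09
ca-ca-c   64.60  120.33
ca-c -o   68.72  123.44
ca-c -oh  69.84  112.94
n -c -o   74.22  123.05
c3-c -o   68.03  123.11
c3-c -oh  69.04  112.20
o -c -o   77.95  130.25
o -c -oh  75.93  121.62
c -oh-ho  49.77  105.97
c3-n -c   63.44  120.69
c -n -hn  48.33  118.46
c3-n -hn  47.13  117.68
hn-n -hn  39.60  117.95
c -n -c3  63.44  120.69
c3-n -c3  64.01  118.17
c -c3-h1  47.63  109.68
c -c3-hc  47.20  109.77
c -c3-c3  63.79  110.53
c -c3-n   66.95  110.78
n -c3-h1  49.84  109.09
n -c3-hc  49.84  109.09
n -c3-c3  66.18  110.38
n3-c3-h1  49.65  109.88
c3-c3-n3  66.18  110.38
c3-n3-hn  47.13  109.92
hn-n3-hn  40.52  107.13
c3-c3-f   66.22  109.41
c3-c3-cl  58.35  110.43
c3-c3-br  56.34  110.74
f -c3-h1  50.20  109.35
cl-c3-h1  43.44  107.47
br-c3-h1  42.12  106.55
f -c3-cl  56.78  110.21
f -c3-br  55.30  110.16
cl-c3-br  51.10  111.10
c2-c2-ha  50.44  120.94
c2-c2-c3  65.65  123.42
ha-c2-ha  37.94  117.66
c2-c3-hc  46.99  110.49
c2-c3-c3  63.62  111.55

DIHE
X -c3-c3-X    1    0.1556  0.0    3.0
X -c3-oh-X    1    0.1667  0.0    3.0
X -c3-os-X    1    0.3833  0.0    3.0
X -c3-n3-X    1    0.3000  0.0    3.0
X -c3-n -X    1    0.0000  0.0    3.0
X -c -n -X    1    2.5000  180.0  2.0
X -ca-ca-X    1    3.6250  180.0  2.0
X -ca-c3-X    1    0.0000  0.0    2.0
X -ca-oh-X    1    0.9000  180.0  2.0
X -ca-c -X    1    1.0000  180.0  2.0
X -c -c3-X    1    0.0000  180.0  2.0
X -c -oh-X    1    2.3000  180.0  2.0
X -c -os-X    1    2.7000  180.0  2.0
X -c2-c2-X    1    6.6500  180.0  2.0
X -c2-c3-X    1    0.0000  0.0    3.0
X -ca-nb-X    1    4.8000  180.0  2.0

NONBON
hc  1.4870  0.0157
h1  1.3870  0.0157
ha  1.4590  0.0150
hn  0.6000  0.0157
ho  0.6000  0.0157
hs  0.6000  0.0157
c   1.9080  0.0860
c1  1.9080  0.2100
c2  1.9080  0.0860
c3  1.9080  0.1094
ca  1.9080  0.0860
n   1.8240  0.1700
n3  1.8240  0.1700
nb  1.8240  0.1700
o   1.6612  0.2100
oh  1.7210  0.2104
os  1.6837  0.1700
s   2.0000  0.2500
p   2.1000  0.2000
f   1.7500  0.0610
cl  1.9480  0.2650
br  2.0200  0.4200
i   2.1500  0.5000
Zn  1.1000  0.0125
Mg  0.7926  0.8947
Ca  1.7131  0.4598
Na  1.8680  0.0028
K   2.6580  0.0003
Fe  1.2000  0.0500
Mn  1.3000  0.0500
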