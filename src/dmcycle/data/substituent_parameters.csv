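X,sigma_m,sigma_p,beta,dG_transfer_kJmol,polarity_class,provenance
H,0.00,0.00,0.0,-16.0,non-polar,"sigma: canonical Hammett compilation; transfer: literature hexadecane/water partition of PhX (NOT from the source study)"
Me,-0.07,-0.17,0.0,-19.0,non-polar,"sigma: canonical Hammett compilation; transfer: literature hexadecane/water partition of PhX (NOT from the source study)"
Et,-0.07,-0.15,0.0,-22.1,non-polar,"sigma: canonical Hammett compilation; transfer: literature hexadecane/water partition of PhX (NOT from the source study)"
iPr,-0.04,-0.15,0.0,-24.9,non-polar,"sigma: canonical Hammett compilation; transfer: literature hexadecane/water partition of PhX (NOT from the source study)"
F,0.34,0.06,0.0,-16.3,non-polar,"sigma: canonical Hammett compilation; transfer: literature hexadecane/water partition of PhX (NOT from the source study)"
Cl,0.37,0.23,0.0,-19.7,non-polar,"sigma: canonical Hammett compilation; transfer: literature hexadecane/water partition of PhX (NOT from the source study)"
Br,0.39,0.23,0.0,-21.0,non-polar,"sigma: canonical Hammett compilation; transfer: literature hexadecane/water partition of PhX (NOT from the source study)"
CF3,0.43,0.54,0.0,,non-polar,"sigma: canonical Hammett compilation; no packaged transfer value"
NO2,0.71,0.78,5.2,-12.6,polar,"sigma: canonical Hammett compilation; beta: H-bond acceptor scale, approximate; transfer: literature (NOT from the source study)"
OMe,0.12,-0.27,4.6,-16.0,polar,"sigma: canonical Hammett compilation; beta: H-bond acceptor scale, approximate; transfer: literature (NOT from the source study)"
NMe2,-0.16,-0.83,5.0,-18.8,polar,"sigma: canonical Hammett compilation; beta: H-bond acceptor scale, approximate; transfer: literature (NOT from the source study)"
CHO,0.35,0.42,5.2,-9.1,polar,"sigma: canonical Hammett compilation; beta: H-bond acceptor scale, approximate; transfer: literature (NOT from the source study)"
COMe,0.38,0.50,5.8,-10.8,polar,"sigma: canonical Hammett compilation; beta: H-bond acceptor scale, approximate; transfer: literature (NOT from the source study)"
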