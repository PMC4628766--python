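file,G1,G2,G3,R1,R2,R3
alb18an,2,3,3,2,3,3
gpc1nal,0,0,0,0,0,0
lba15an,2,0,0,1,0,0
pmc26an,2,3,3,2,2,2
amc14an,1,3,3,1,3,3
gsb11an,3,3,3,3,3,3
lba24an,2,0,0,1,0,0
pmd25an,2,3,2,2,3,2
aos21an,3,3,3,3,3,3
gxl21an,1,0,0,1,0,0
ldp1nal,1,0,0,0,0,0
pmf03an,2,1,1,2,1,1
axd19an,0,0,0,0,0,0
gxt10an,3,3,3,3,3,3
les15an,3,3,3,3,0,0
rcc11an,2,3,3,2,2,2
axh1nal,0,0,0,0,0,0
gzz1nal,1,0,0,1,0,0
lgm01an,1,0,0,1,0,0
rhg1nal,0,1,0,0,1,0
axt13an,1,1,1,1,0,1
hbl1nal,1,0,0,1,0,0
ljh06an,2,2,2,2,2,2
rhm1nal,0,0,0,0,0,0
bah13an,1,3,2,1,3,2
hjh07an,2,3,3,2,3,3
ljs31an,2,1,1,1,1,0
rhp12an,2,3,2,2,3,2
bef05an,2,3,3,2,0,0
hlm24an,1,2,2,1,2,2
lla1nal,1,0,0,0,0,0
rjf22an,2,3,3,2,3,3
bjb1nal,0,0,0,0,0,0
hxi29an,1,3,2,1,3,2
llm22an,3,3,2,3,3,2
rjl28an,3,3,2,2,3,2
bjv1nal,0,0,0,0,0,0
hxl58an,1,0,0,1,0,0
lmv1nal,1,0,0,1,0,0
rjr15an,1,1,1,1,1,1
bkb13an,1,0,1,2,0,1
jaf1nal,0,0,0,0,0,0
lmw1nal,1,0,0,0,0,0
rjs1nal,0,0,0,0,0,0
blb03an,2,3,2,2,3,2
jan1nal,1,1,1,1,1,1
lnc11an,1,0,0,0,0,0
rjz16an,1,0,0,1,0,0
bpf03an,1,2,1,1,2,1
jap02an,2,1,1,2,0,1
lrd21an,1,0,0,0,0,0
rmb07an,2,3,3,2,3,3
bsg13an,1,1,1,1,1,1
jap1nal,0,0,0,0,0,0
lvd28an,2,3,2,2,2,2
rpj15an,3,3,3,3,3,3
cac10an,2,3,3,2,0,0
jcc10an,2,2,2,2,2,2
lwr18an,1,3,3,1,0,0
rpq20an,2,3,3,2,3,3
cad1nal,0,0,0,0,0,0
jcr01an,3,3,3,3,3,3
lxc01an,2,2,2,2,0,0
rtl17an,1,0,1,1,0,1
cak25an,2,1,1,2,1,1
jeg1nal,0,0,0,0,0,0
lxc06an,3,3,3,3,3,3
rwc23an,2,3,3,2,3,3
ceb1nal,0,0,0,0,0,0
jeg29an,2,3,2,2,0,0
lxr15an,3,3,2,3,3,2
rxm15an,1,0,0,1,0,0
cls31an,2,1,1,2,1,1
jfg08an,3,3,3,3,3,3
mab06an,2,1,1,2,1,1
rxp02an,1,3,3,1,3,3
cma06an,1,2,1,1,2,1
jfn21an,3,2,2,3,2,2
mam08an,2,3,3,2,3,3
sac10an,2,3,3,2,3,3
cmr06an,0,0,0,0,0,0
jhw29an,2,1,1,2,1,1
mam1nal,0,0,0,0,0,0
sae01an,1,0,0,1,0,0
crm12an,3,3,3,3,2,2
jkr1nal,1,0,0,1,0,0
mas1nal,0,0,0,0,0,0
sav18an,3,3,3,3,3,3
ctb30an,2,2,1,2,1,1
jld24an,2,3,2,2,3,2
mcb1nal,1,0,0,1,0,0
sbf11an,0,0,0,0,0,0
daj1nal,0,0,0,0,0,0
jls11an,2,1,1,2,1,1
mcw21an,2,1,1,2,1,1
scc15an,3,3,3,3,0,1
dap17an,2,2,1,2,2,1
jmc18an,1,0,0,1,0,0
mec06an,2,0,0,2,0,0
sck1nal,1,0,0,1,0,0
das30an,1,,1,1,,1
jmc1nal,1,0,0,1,0,0
mec28an,2,2,1,1,2,1
sct1nal,1,0,0,1,0,0
dbf18an,2,2,1,2,2,1
jpp27an,3,3,3,3,0,0
mfc20an,3,3,3,2,3,3
seb1nal,1,0,0,1,0,0
dfp1nal,0,0,0,0,0,0
jrf30an,1,0,0,1,0,0
mfm1nal,1,0,0,1,0,0
sec02an,2,0,1,2,0,1
djg1nal,0,0,0,0,0,0
jth1nal,1,0,0,0,0,0
mju1nal,0,0,0,0,0,0
sef10an,1,0,0,1,0,0
djp04an,2,2,2,2,2,2
jtm05an,1,2,1,1,2,1
mpb23an,3,3,3,3,3,3
seg18an,2,1,1,2,1,1
dma1nal,0,0,0,0,0,0
jxc1nal,1,0,0,0,0,0
mpf25an,1,2,1,1,2,1
sek06an,2,2,1,2,2,1
dmc03an,2,3,2,2,0,0
jxc21an,2,0,0,2,0,0
mps09an,2,0,1,2,0,1
shd04an,3,3,3,3,3,3
dmp04an,2,2,2,2,2,2
jxd30an,1,1,1,0,1,1
mrb11an,1,3,2,1,3,2
sis1nal,0,0,0,0,0,0
drc15an,2,2,2,2,0,0
jxf11an,3,3,3,3,3,3
mrc20an,2,3,2,2,3,2
sjd28an,1,1,1,1,1,1
dsc25an,3,3,3,3,0,0
kab03an,1,0,0,1,0,0
mwd28an,2,3,2,2,3,2
slc1nal,2,0,0,1,0,0
dsw14an,2,,1,2,,1
kac07an,1,0,0,1,0,0
mxb1nal,0,0,0,0,0,0
slc23an,2,0,1,1,0,1
dvd19an,3,3,3,3,3,3
kan1nal,0,0,0,0,0,0
mxc10an,2,2,2,2,2,2
slg05an,1,0,0,1,0,0
dwk04an,2,2,2,2,2,2
kcg23an,2,2,1,2,2,1
mxn24an,1,0,0,1,0,0
sma08an,3,3,3,3,3,3
dws1nal,0,0,0,0,0,0
kcg25an,1,0,0,1,0,0
mxz1nal,1,0,0,0,0,0
sws04an,3,2,2,3,2,2
eab27an,3,3,3,3,3,3
kdb23an,2,2,2,2,2,2
nfg08an,2,2,1,1,2,1
sxv1nal,1,0,0,1,0,0
eas11an,1,2,1,1,2,1
kjb19an,2,3,3,2,3,3
njs06an,2,2,1,2,2,1
tab21an,3,3,3,3,3,3
eas15an,3,3,3,3,3,3
klc06an,2,3,3,2,0,0
njs1nal,1,0,0,1,0,0
tdh12an,2,2,1,2,2,1
edc1nal,1,0,0,1,0,0
klc09an,2,3,2,2,3,2
nkr03an,1,0,0,1,0,0
tlp13an,2,2,2,2,2,2
eec04an,3,3,3,3,2,2
kld26an,2,2,1,2,2,1
nlc08an,2,2,1,2,2,1
tls09an,2,2,2,2,2,2
eed07an,3,3,3,3,3,3
kmc22an,2,1,1,2,1,0
nmb28an,2,3,2,1,3,2
tpp24an,1,0,0,1,0,0
ejc1nal,0,0,0,0,0,0
kms29an,2,3,3,2,3,3
nmc22an,2,2,1,1,1,1
tps16an,1,,1,1,,1
ejh24an,3,3,3,3,0,1
kmw05an,3,3,3,3,1,1
nml15an,0,1,1,0,1,1
txn1nal,1,,0,1,,0
emp27an,2,2,2,2,2,2
kps25an,0,2,1,0,2,1
nmv07an,3,3,3,3,0,0
vaw07an,3,3,3,3,3,3
ess05an,1,0,0,1,0,0
ktj26an,3,3,3,3,3,3
oab28an,1,3,3,2,3,3
vmc1nal,1,0,0,1,0,0
eww05an,2,2,2,2,2,2
kxb17an,3,3,3,3,3,3
ovk1nal,0,0,0,0,0,0
wcb24an,1,0,0,1,0,0
fmb1nal,0,0,0,0,0,0
kxh30an,3,3,3,3,3,3
pat10an,2,3,3,1,3,3
wdk1nal,0,0,0,0,0,0
fmr17an,3,3,3,3,3,3
lac02an,2,1,1,2,0,1
pbd1nal,1,0,0,1,0,0
wfc07an,2,3,2,2,3,2
fxc12an,1,2,2,1,2,2
lad13an,1,2,1,1,2,1
pca1nal,1,0,0,0,0,0
wjb06an,2,0,0,2,0,0
gdr15an,3,3,3,3,0,0
lad1nal,0,0,0,0,0,0
pdo11an,2,3,3,2,3,3
wjp20an,3,3,3,3,3,3
gmm09an,3,3,3,3,3,3
lai04an,1,3,2,1,3,2
pgb16an,1,1,1,1,1,1
wpb30an,2,1,1,2,1,1
gms05an,2,3,3,2,3,3
lap05an,1,3,3,1,3,3
plw14an,2,2,2,2,2,2
wxe04an,3,3,3,3,3,3
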