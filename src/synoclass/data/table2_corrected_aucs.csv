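pair,marker,method,corrected_auc,sig
SeA:RA,CD15,absolute,0.92,**
SeA:RA,CD15,relative,0.94,**
SeA:RA,CD68,absolute,0.60,
SeA:RA,CD68,relative,0.59,
SeA:RA,CD3,absolute,0.52,
SeA:RA,CD3,relative,0.58,
SeA:RA,CD20,absolute,0.60,
SeA:RA,CD20,relative,0.62,
SeA:RA,CD38,absolute,0.72,
SeA:RA,CD38,relative,0.79,*
SeA:RA,TIC,tic,0.52,
SeA:EA,CD15,absolute,0.97,**
SeA:EA,CD15,relative,0.90,**
SeA:EA,CD68,absolute,0.54,
SeA:EA,CD68,relative,0.57,
SeA:EA,CD3,absolute,0.71,
SeA:EA,CD3,relative,0.65,
SeA:EA,CD20,absolute,0.56,
SeA:EA,CD20,relative,0.52,
SeA:EA,CD38,absolute,0.55,
SeA:EA,CD38,relative,0.66,
SeA:EA,TIC,tic,0.65,
SeA:OA,CD15,absolute,1.00,**
SeA:OA,CD15,relative,0.97,**
SeA:OA,CD68,absolute,1.00,**
SeA:OA,CD68,relative,0.83,**
SeA:OA,CD3,absolute,0.97,**
SeA:OA,CD3,relative,0.63,
SeA:OA,CD20,absolute,0.85,**
SeA:OA,CD20,relative,0.69,
SeA:OA,CD38,absolute,0.87,**
SeA:OA,CD38,relative,0.73,
SeA:OA,TIC,tic,0.99,**
SeA:Orth.A,CD15,absolute,1.00,**
SeA:Orth.A,CD15,relative,0.92,*
SeA:Orth.A,CD68,absolute,1.00,**
SeA:Orth.A,CD68,relative,0.98,**
SeA:Orth.A,CD3,absolute,1.00,**
SeA:Orth.A,CD3,relative,0.59,
SeA:Orth.A,CD20,absolute,1.00,**
SeA:Orth.A,CD20,relative,0.94,*
SeA:Orth.A,CD38,absolute,1.00,**
SeA:Orth.A,CD38,relative,0.94,*
SeA:Orth.A,TIC,tic,1.00,**
SeA:N,CD15,absolute,1.00,**
SeA:N,CD15,relative,0.99,**
SeA:N,CD68,absolute,1.00,**
SeA:N,CD68,relative,0.99,**
SeA:N,CD3,absolute,1.00,**
SeA:N,CD3,relative,0.68,
SeA:N,CD20,absolute,0.99,**
SeA:N,CD20,relative,0.76,
SeA:N,CD38,absolute,1.00,**
SeA:N,CD38,relative,0.94,**
SeA:N,TIC,tic,1.00,**
RA:EA,CD15,absolute,0.62,
RA:EA,CD15,relative,0.57,
RA:EA,CD68,absolute,0.54,
RA:EA,CD68,relative,0.66,
RA:EA,CD3,absolute,0.70,
RA:EA,CD3,relative,0.64,
RA:EA,CD20,absolute,0.62,
RA:EA,CD20,relative,0.58,
RA:EA,CD38,absolute,0.67,
RA:EA,CD38,relative,0.63,
RA:EA,TIC,tic,0.67,
RA:OA,CD15,absolute,0.96,**
RA:OA,CD15,relative,0.72,*
RA:OA,CD68,absolute,0.97,**
RA:OA,CD68,relative,0.85,**
RA:OA,CD3,absolute,0.94,**
RA:OA,CD3,relative,0.59,
RA:OA,CD20,absolute,0.90,**
RA:OA,CD20,relative,0.75,*
RA:OA,CD38,absolute,0.97,**
RA:OA,CD38,relative,0.91,**
RA:OA,TIC,tic,0.99,**
RA:Orth.A,CD15,absolute,0.98,**
RA:Orth.A,CD15,relative,0.58,
RA:Orth.A,CD68,absolute,1.00,**
RA:Orth.A,CD68,relative,0.93,**
RA:Orth.A,CD3,absolute,0.98,**
RA:Orth.A,CD3,relative,0.69,
RA:Orth.A,CD20,absolute,0.97,**
RA:Orth.A,CD20,relative,0.95,**
RA:Orth.A,CD38,absolute,1.00,**
RA:Orth.A,CD38,relative,1.00,**
RA:Orth.A,TIC,tic,1.00,**
RA:N,CD15,absolute,1.00,**
RA:N,CD15,relative,0.87,**
RA:N,CD68,absolute,1.00,**
RA:N,CD68,relative,0.97,**
RA:N,CD3,absolute,0.99,**
RA:N,CD3,relative,0.61,
RA:N,CD20,absolute,0.97,**
RA:N,CD20,relative,0.82,**
RA:N,CD38,absolute,1.00,**
RA:N,CD38,relative,0.99,**
RA:N,TIC,tic,1.00,**
EA:OA,CD15,absolute,0.88,**
EA:OA,CD15,relative,0.65,
EA:OA,CD68,absolute,0.85,**
EA:OA,CD68,relative,0.70,
EA:OA,CD3,absolute,0.90,**
EA:OA,CD3,relative,0.54,
EA:OA,CD20,absolute,0.73,
EA:OA,CD20,relative,0.59,
EA:OA,CD38,absolute,0.90,**
EA:OA,CD38,relative,0.82,*
EA:OA,TIC,tic,0.95,**
EA:Orth.A,CD15,absolute,0.89,*
EA:Orth.A,CD15,relative,0.52,
EA:Orth.A,CD68,absolute,0.97,**
EA:Orth.A,CD68,relative,0.82,
EA:Orth.A,CD3,absolute,0.93,**
EA:Orth.A,CD3,relative,0.72,
EA:Orth.A,CD20,absolute,0.77,
EA:Orth.A,CD20,relative,0.77,
EA:Orth.A,CD38,absolute,1.00,**
EA:Orth.A,CD38,relative,0.97,*
EA:Orth.A,TIC,tic,1.00,**
EA:N,CD15,absolute,0.99,**
EA:N,CD15,relative,0.85,*
EA:N,CD68,absolute,0.99,**
EA:N,CD68,relative,0.84,*
EA:N,CD3,absolute,0.99,**
EA:N,CD3,relative,0.51,
EA:N,CD20,absolute,0.78,*
EA:N,CD20,relative,0.69,
EA:N,CD38,absolute,1.00,**
EA:N,CD38,relative,0.98,**
EA:N,TIC,tic,1.00,**
OA:Orth.A,CD15,absolute,0.62,
OA:Orth.A,CD15,relative,0.61,
OA:Orth.A,CD68,absolute,0.83,*
OA:Orth.A,CD68,relative,0.53,
OA:Orth.A,CD3,absolute,0.60,
OA:Orth.A,CD3,relative,0.76,
OA:Orth.A,CD20,absolute,0.68,
OA:Orth.A,CD20,relative,0.66,
OA:Orth.A,CD38,absolute,0.72,
OA:Orth.A,CD38,relative,0.66,
OA:Orth.A,TIC,tic,0.83,*
OA:N,CD15,absolute,0.80,**
OA:N,CD15,relative,0.71,
OA:N,CD68,absolute,0.91,**
OA:N,CD68,relative,0.59,
OA:N,CD3,absolute,0.79,**
OA:N,CD3,relative,0.50,
OA:N,CD20,absolute,0.67,
OA:N,CD20,relative,0.57,
OA:N,CD38,absolute,0.82,**
OA:N,CD38,relative,0.78,**
OA:N,TIC,tic,0.92,**
Orth.A:N,CD15,absolute,0.72,
Orth.A:N,CD15,relative,0.74,
Orth.A:N,CD68,absolute,0.64,
Orth.A:N,CD68,relative,0.68,
Orth.A:N,CD3,absolute,0.72,
Orth.A:N,CD3,relative,0.78,
Orth.A:N,CD20,absolute,0.53,
Orth.A:N,CD20,relative,0.58,
Orth.A:N,CD38,absolute,0.74,
Orth.A:N,CD38,relative,0.72,
Orth.A:N,TIC,tic,0.67,
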